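#!/usr/bin/env python
"""Generate the synthetic survey data both risk tracks consume.

Draws station concentration tables (10 sediment / 20 seawater stations,
two seasonal campaigns, 3 replicates) and a 336-record chronic toxicity
table from the bundled Laizhou Bay scenario, and archives the scenario
files alongside so the exact generating conditions travel with the data.
Writes results/simulated/.
"""

import argparse
from pathlib import Path

from ecorisk.core import write_concentrations, write_toxicity
from ecorisk.synthetic import gen_concentrations, gen_toxicity, laizhou_scenario

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/simulated"))
args = parser.parse_args()

args.out.mkdir(parents=True, exist_ok=True)
conc_sc, tox_sc = laizhou_scenario()
conc = gen_concentrations(conc_sc, seed=args.seed)
tox = gen_toxicity(tox_sc, seed=args.seed)
write_concentrations(conc, args.out / "concentrations.csv")
write_toxicity(tox, args.out / "toxicity.csv")
conc_sc.save(args.out / "concentrations.yaml")
tox_sc.save(args.out / "toxicity.yaml")

n_sed = sum(r.matrix.value == "sediment" for r in conc)
print(f"seed {args.seed}: {len(conc)} concentration records "
      f"({n_sed} sediment, {len(conc) - n_sed} seawater), {len(tox)} toxicity records")
print(f"written to {args.out}/")
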