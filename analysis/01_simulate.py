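"""Generate the default synthetic billing study and write its tables.

The default configuration emulates the structure of the physician-recruitment
setting this package targets: 40 hospitals on 5 trial steps, ~360 invited
hospitalists, half billing at more than one hospital, and participation
outcomes drawn from the sequential peer-influence model.
"""

import argparse
from pathlib import Path

from peernet.simulate import SimConfig, simulate_study


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results/data")
    args = ap.parse_args()

    study = simulate_study(SimConfig(seed=args.seed))
    study.write(args.out)
    phys = study.physicians
    print(f"wrote {args.out}: {len(study.billing)} billing rows, "
          f"{len(phys)} physicians at {len(study.hospitals)} hospitals")
    print(f"participation: {phys['participated'].mean():.2%} "
          f"({int(phys['participated'].sum())}/{len(phys)})")
    multi = (study.affiliations.groupby("physician_id").size() > 1).mean()
    print(f"multi-site physicians: {multi:.1%}")


if __name__ == "__main__":
    main()
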