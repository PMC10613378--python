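"""Within- and across-hospital peer-participation exposures.

The across exposure is step-masked (same trial step or earlier) before
row-normalization, then ln(1 + 100p) transformed for modeling.
"""

import argparse
from pathlib import Path

import pandas as pd

from peernet.exposure import build_exposure_table
from peernet.network import (
    attribute_physicians,
    binarize,
    build_encounter_matrix,
    project_shared_patients,
    read_billing,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--billing", default="results/data/billing.csv")
    ap.add_argument("--physicians", default="results/data/physicians.csv")
    ap.add_argument("--hospitals", default="results/data/hospitals.csv")
    ap.add_argument("--out", default="results/exposures.csv")
    args = ap.parse_args()

    billing = read_billing(args.billing)
    B = binarize(project_shared_patients(build_encounter_matrix(billing)), 0.0)
    attr = attribute_physicians(billing)
    phys = pd.read_csv(args.physicians).set_index("physician_id")
    steps = pd.read_csv(args.hospitals).set_index("hospital_id")["step"]

    table = build_exposure_table(B, attr, phys["participated"].astype(float), steps)
    Path(args.out).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out)
    defined = ~table["wy_ac_undefined"]
    print(f"wrote {args.out}")
    print(f"within exposure: mean {table['wy_wi'].mean():.1f}% "
          f"({int(table['wy_wi_undefined'].sum())} undefined)")
    print(f"across exposure: mean {table.loc[defined, 'wy_ac'].mean():.3f} "
          f"({int((~defined).sum())} undefined of {len(table)})")


if __name__ == "__main__":
    main()
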