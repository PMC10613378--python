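"""Univariate screens and the fixed-/random-effects participation models.

The fixed-effects model includes the within-hospital exposure (on its 0-100
scale); the random-effects model excludes it and lets the hospital intercept
absorb hospital-level participation culture, reflecting the simultaneity of
same-hospital decisions.
"""

import argparse
from pathlib import Path

import pandas as pd

from peernet.design import covariate_frame
from peernet.exposure import build_exposure_table
from peernet.models import ModelSpec, fit, reduce_model, univariate_tests
from peernet.network import (
    attribute_physicians,
    binarize,
    build_encounter_matrix,
    project_shared_patients,
    read_billing,
)
from peernet.pipeline import render_fit_table


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--billing", default="results/data/billing.csv")
    ap.add_argument("--physicians", default="results/data/physicians.csv")
    ap.add_argument("--hospitals", default="results/data/hospitals.csv")
    ap.add_argument("--alpha", type=float, default=0.05)
    ap.add_argument("--out", default="results/models")
    args = ap.parse_args()

    outdir = Path(args.out)
    outdir.mkdir(parents=True, exist_ok=True)
    billing = read_billing(args.billing)
    B = binarize(project_shared_patients(build_encounter_matrix(billing)), 0.0)
    attr = attribute_physicians(billing)
    phys = pd.read_csv(args.physicians).set_index("physician_id")
    steps = pd.read_csv(args.hospitals).set_index("hospital_id")["step"]
    exposures = build_exposure_table(B, attr, phys["participated"].astype(float), steps)

    frame = covariate_frame(phys.loc[exposures.index])
    frame["participated"] = phys.loc[exposures.index, "participated"].astype(float)
    frame["primary_hospital"] = pd.Series(attr.primary, index=attr.physicians)
    frame = frame.join(exposures)
    frame["sex"] = phys.loc[exposures.index, "sex"]
    frame["age_raw"] = phys.loc[exposures.index, "age"]
    frame["n_hospitals"] = frame["n_nonprimary"] + 1

    uni = univariate_tests(
        frame,
        continuous=("age_raw", "n_hospitals", "years_org", "shannon",
                    "degree_within", "degree_across", "wy_wi", "wy_ac"),
        categorical=("sex",),
    )
    uni.to_csv(outdir / "univariate.csv", index=False)
    print("univariate screens written; smallest p:",
          f"{uni['p'].min():.2e} ({uni.loc[uni['p'].idxmin(), 'variable']})")

    fixed = ModelSpec(
        outcome="participated",
        terms=("age", "age_observed", "years_org", "shannon", "wy_wi", "wy_ac_t"),
        interactions=(("wy_ac_t", "shannon"),),
    )
    mixed = ModelSpec(
        outcome="participated",
        terms=("age", "age_observed", "years_org", "shannon", "wy_ac_t"),
        interactions=(("wy_ac_t", "shannon"),),
        random_intercept="primary_hospital",
    )
    for name, spec in (("fixed_effects", fixed), ("random_effects", mixed)):
        result = fit(spec, frame)
        table = render_fit_table(result)
        table.to_csv(outdir / f"model_{name}.csv", index=False)
        print(f"\n{name} model (n={result.n}):")
        print(table.to_string(index=False))
        if result.tau is not None:
            print(f"random-intercept SD tau = {result.tau:.3f}")

    final, trace, result = reduce_model(fixed, frame, alpha=args.alpha)
    render_fit_table(result).to_csv(outdir / "model_reduced.csv", index=False)
    removed = [step["removed"] for step in trace]
    print(f"\nbackward elimination removed {removed}; kept {list(final.terms)}")


if __name__ == "__main__":
    main()
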