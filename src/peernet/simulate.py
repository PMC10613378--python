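"""Synthetic physician-billing study generator.

Emulates the structure of a stepped-wedge physician-recruitment study: ~40
hospitals randomized across 5 steps, ~350 invited hospitalists with
near-complete patient sharing inside each hospital, a minority of physicians
billing at 2-9 hospitals, and participation outcomes drawn from the
random-intercept logistic peer-effect model

    logit(pi_il) = b0 + b1'X_il + b2*H_i + b3*WY_wi,i
                   + (b4 + b5*N_i)*WY_ac,i + theta_l,
    theta_l ~ Normal(0, tau^2),

where H_i is the Shannon billing diversity, N_i the number of non-primary
billing hospitals, WY_wi the within-hospital peer participation exposure
(0-100 scale) and WY_ac the step-masked across-hospital exposure
(ln(1 + 100p) transformed).

Because within-hospital decisions are simultaneous in the real study (a
source of endogeneity), the generator resolves them with a random sequential
decision process: hospitals are processed in trial-step order and physicians
within a hospital decide one at a time in random order, each seeing only the
outcomes of already-decided eligible peers.  The exposures actually used at
each decision are recorded in :class:`SimTruth` for parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import COVARIATES, covariate_frame
from .exceptions import ConfigurationError, StructuralError
from .exposure import transform_across
from .network import attribute_physicians, binarize, build_encounter_matrix, project_shared_patients

PHYSICIAN_SCHEMA = (
    "physician_id",
    "primary_hospital_id",
    "age",
    "age_observed",
    "sex",
    "years_org",
    "invited",
    "participated",
)


@dataclass(frozen=True)
class Coefficients:
    """Generating coefficients of the participation model.

    Defaults reflect the effect sizes a study of this design reports: odds
    ratios of ~0.96 per year of age, ~6 for age being observed, ~1.6 per year
    of tenure, ~7 per unit of Shannon diversity, 1.05 per percent of within
    peers participating, 1 for the across main effect and ~1.12 for its
    modification, all on the log-odds scale.  The intercept is calibrated so
    the default configuration yields an overall participation rate near 47%.
    """

    intercept: float = -5.35
    age: float = -0.041
    age_observed: float = 1.82
    sex_male: float = 0.0
    years_org: float = 0.45
    shannon: float = 1.98
    within: float = 0.0488
    across: float = 0.0
    across_interaction: float = 0.113
    interaction_var: str = "n_nonprimary"  # or "shannon"

    def covariates(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in COVARIATES}


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic study; identical configs (including
    seed) yield byte-identical outputs."""

    n_hospitals: int = 40
    n_steps: int = 5
    physicians_per_hospital: tuple[int, int] = (7, 11)
    multi_site_fraction: float = 0.5
    max_sites: int = 9
    site_share_concentration: float = 0.2
    patients_per_hospital: tuple[int, int] = (100, 150)
    encounters_per_patient: tuple[int, int] = (2, 6)
    beta: Coefficients = field(default_factory=Coefficients)
    tau: float = 0.126
    age_missing_rate: float = 0.146
    male_fraction: float = 0.623
    date_window: tuple[str, str] = ("2019-01-01", "2021-05-31")
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        def check_range(name, lo_hi, minimum=1):
            lo, hi = lo_hi
            if not (minimum <= lo <= hi):
                raise ConfigurationError(
                    f"{name}: expected {minimum} <= low <= high, got {lo_hi}"
                )

        if self.n_hospitals < 1:
            raise ConfigurationError(f"n_hospitals must be >= 1, got {self.n_hospitals}")
        if self.n_steps < 1:
            raise ConfigurationError(f"n_steps must be >= 1, got {self.n_steps}")
        check_range("physicians_per_hospital", self.physicians_per_hospital)
        check_range("patients_per_hospital", self.patients_per_hospital)
        check_range("encounters_per_patient", self.encounters_per_patient)
        for name in ("multi_site_fraction", "age_missing_rate", "male_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.max_sites < 1:
            raise ConfigurationError(f"max_sites must be >= 1, got {self.max_sites}")
        if self.multi_site_fraction > 0 and (self.max_sites < 2 or self.n_hospitals < 2):
            raise ConfigurationError(
                "multi_site_fraction > 0 requires max_sites >= 2 and n_hospitals >= 2"
            )
        if self.site_share_concentration <= 0:
            raise ConfigurationError(
                f"site_share_concentration must be positive, got {self.site_share_concentration}"
            )
        if self.tau < 0:
            raise ConfigurationError(f"tau must be nonnegative, got {self.tau}")
        start, end = (dt.date.fromisoformat(d) for d in self.date_window)
        if start > end:
            raise ConfigurationError(f"date_window start {start} after end {end}")

    def rng(self, stage: int) -> np.random.Generator:
        """Stage-specific generator split deterministically from the seed."""
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(3)[stage])


@dataclass
class Population:
    physicians: pd.DataFrame
    hospitals: pd.DataFrame
    affiliations: pd.DataFrame  # physician_id, hospital_id, share


@dataclass
class SimTruth:
    """Generating coefficients, hospital effects and the latent decision
    process of one synthetic study."""

    beta: Coefficients
    tau: float
    hospital_effects: dict[str, float]
    adoption_order: list[str]
    true_exposures: pd.DataFrame

    def to_json(self, path) -> None:
        payload = {
            "beta": dataclasses.asdict(self.beta),
            "tau": self.tau,
            "hospital_effects": self.hospital_effects,
            "adoption_order": self.adoption_order,
            "true_exposures": self.true_exposures.reset_index().to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        payload = json.loads(Path(path).read_text())
        exposures = pd.DataFrame(payload["true_exposures"]).set_index("physician_id")
        return cls(
            beta=Coefficients(**payload["beta"]),
            tau=payload["tau"],
            hospital_effects=payload["hospital_effects"],
            adoption_order=payload["adoption_order"],
            true_exposures=exposures,
        )


@dataclass
class Study:
    """A complete synthetic study: tables, billing rows and generating truth."""

    physicians: pd.DataFrame
    hospitals: pd.DataFrame
    affiliations: pd.DataFrame
    billing: pd.DataFrame
    truth: SimTruth

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        billing = self.billing.copy()
        billing["date"] = pd.to_datetime(billing["date"]).dt.date.astype(str)
        billing.to_csv(outdir / "billing.csv", index=False)
        self.physicians[list(PHYSICIAN_SCHEMA)].to_csv(
            outdir / "physicians.csv", index=False
        )
        self.hospitals.to_csv(outdir / "hospitals.csv", index=False)
        self.truth.to_json(outdir / "truth.json")


def _hospital_ids(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"h{i:0{width}d}" for i in range(1, n + 1)]


def generate_population(config: SimConfig) -> Population:
    """Draw hospitals (with balanced step assignments) and physicians.

    Each physician has a home hospital; a ``multi_site_fraction`` share of
    physicians additionally bill at 1-8 other hospitals, with billing shares
    drawn from a symmetric Dirichlet distribution.  The largest share defines
    the primary hospital.  Site counts beyond the home hospital follow a
    truncated geometric distribution, keeping multi-site physicians mostly at
    2-4 hospitals with a tail out to ``max_sites``.
    """
    rng = config.rng(0)
    hospitals = _hospital_ids(config.n_hospitals)
    steps = np.tile(np.arange(1, config.n_steps + 1), config.n_hospitals // config.n_steps + 1)
    steps = rng.permutation(steps[: config.n_hospitals])
    hospital_table = pd.DataFrame({"hospital_id": hospitals, "step": steps})

    lo, hi = config.physicians_per_hospital
    counts = rng.integers(lo, hi + 1, size=config.n_hospitals)
    rows, aff_rows = [], []
    pid = 0
    for h_idx, home in enumerate(hospitals):
        for _ in range(counts[h_idx]):
            pid += 1
            physician = f"d{pid:04d}"
            if config.max_sites >= 2 and rng.random() < config.multi_site_fraction:
                extra = min(int(rng.geometric(0.55)), config.max_sites - 1)
            else:
                extra = 0
            others = [h for h in hospitals if h != home]
            sites = [home] + (
                list(rng.choice(others, size=extra, replace=False)) if extra else []
            )
            if len(sites) == 1:
                shares = np.array([1.0])
            else:
                shares = rng.dirichlet(
                    np.full(len(sites), config.site_share_concentration)
                )
            # primary = largest share, lexicographic tie-break
            order = sorted(range(len(sites)), key=lambda k: (-shares[k], sites[k]))
            primary = sites[order[0]]
            age_observed = int(rng.random() >= config.age_missing_rate)
            age = float(np.clip(rng.normal(42.27, 8.32), 25.0, 75.0))
            rows.append(
                {
                    "physician_id": physician,
                    "primary_hospital_id": primary,
                    "age": round(age, 1) if age_observed else np.nan,
                    "age_observed": age_observed,
                    "sex": "M" if rng.random() < config.male_fraction else "F",
                    "years_org": round(float(np.clip(rng.normal(3.62, 0.9), 0.5, 30.0)), 2),
                    "invited": 1,
                    "participated": np.nan,
                }
            )
            for s, w in zip(sites, shares):
                aff_rows.append(
                    {"physician_id": physician, "hospital_id": s, "share": float(w)}
                )
    physicians = pd.DataFrame(rows)
    affiliations = pd.DataFrame(aff_rows)
    return Population(physicians, hospital_table, affiliations)


def generate_encounters(population: Population, config: SimConfig) -> pd.DataFrame:
    """Draw billing rows (physician_id, patient_id, hospital_id, date).

    Each patient belongs to one hospital; their encounters are assigned to
    physicians billing there with probability proportional to the physicians'
    billing shares at that hospital.  At the default configuration the
    per-hospital patient and encounter volumes are high enough that every
    pair of physicians primarily attributed to a hospital shares at least one
    patient, reproducing the near-complete within-hospital subnetworks
    observed in practice.
    """
    rng = config.rng(1)
    known = set(population.hospitals["hospital_id"])
    if not set(population.affiliations["hospital_id"]).issubset(known):
        raise StructuralError("affiliations reference hospitals absent from the hospital table")
    start, end = (dt.date.fromisoformat(d) for d in config.date_window)
    n_days = (end - start).days + 1
    lo_p, hi_p = config.patients_per_hospital
    lo_e, hi_e = config.encounters_per_patient

    by_hospital = population.affiliations.groupby("hospital_id")
    frames = []
    patient_counter = 0
    for hosp in population.hospitals["hospital_id"]:
        if hosp not in by_hospital.groups:
            continue
        aff = by_hospital.get_group(hosp)
        physicians = aff["physician_id"].to_numpy()
        weights = aff["share"].to_numpy()
        weights = weights / weights.sum()
        n_patients = int(rng.integers(lo_p, hi_p + 1))
        enc_per_patient = rng.integers(lo_e, hi_e + 1, size=n_patients)
        total = int(enc_per_patient.sum())
        patient_ids = np.repeat(
            [f"p{patient_counter + k:06d}" for k in range(1, n_patients + 1)],
            enc_per_patient,
        )
        patient_counter += n_patients
        assigned = rng.choice(physicians, size=total, p=weights)
        day_offsets = rng.integers(0, n_days, size=total)
        frames.append(
            pd.DataFrame(
                {
                    "physician_id": assigned,
                    "patient_id": patient_ids,
                    "hospital_id": hosp,
                    "date": pd.to_datetime(start) + pd.to_timedelta(day_offsets, unit="D"),
                }
            )
        )
    billing = pd.concat(frames, ignore_index=True)
    # every physician bills at least once: an employed hospitalist with zero
    # realized encounters would be unattributable downstream
    billed = set(billing["physician_id"])
    extra = []
    top_site = (
        population.affiliations.sort_values(
            ["physician_id", "share", "hospital_id"], ascending=[True, False, True]
        )
        .groupby("physician_id")
        .first()
    )
    patients_of = {
        h: billing.loc[billing["hospital_id"] == h, "patient_id"].unique()
        for h in set(top_site["hospital_id"])
    }
    for physician in population.physicians["physician_id"]:
        if physician in billed:
            continue
        hosp = top_site.loc[physician, "hospital_id"]
        pool = patients_of.get(hosp, np.array([], dtype=object))
        if len(pool) == 0:
            continue
        extra.append(
            {
                "physician_id": physician,
                "patient_id": pool[int(rng.integers(len(pool)))],
                "hospital_id": hosp,
                "date": pd.to_datetime(start)
                + pd.to_timedelta(int(rng.integers(0, n_days)), unit="D"),
            }
        )
    if extra:
        billing = pd.concat([billing, pd.DataFrame(extra)], ignore_index=True)
    return billing


def _masked_mean(row_mask: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """Uniform average of y over the masked neighbors; flagged if none."""
    idx = np.flatnonzero(row_mask)
    if idx.size == 0:
        return 0.0, True
    return float(y[idx].mean()), False


def generate_outcomes(
    population: Population, billing: pd.DataFrame, config: SimConfig
) -> tuple[pd.Series, SimTruth]:
    """Draw participation outcomes by the sequential peer-influence process.

    Hospitals are processed in trial-step order (ties broken by hospital id);
    within each hospital its primary-attributed physicians decide in a
    uniformly random sequence.  Each decision sees the within-hospital
    exposure over already-decided same-hospital peers and the across-hospital
    exposure over already-decided peers at same-step-or-earlier hospitals,
    then draws Bernoulli(pi) from the logistic model.
    """
    rng = config.rng(2)
    phys = population.physicians.set_index("physician_id", drop=False)
    attr = attribute_physicians(billing)
    missing = set(phys.index) - set(attr.physicians)
    if missing:
        raise StructuralError(
            f"physicians absent from billing records: {sorted(missing)[:5]}"
        )
    order_ids = attr.physicians  # lexicographic, matches network node order
    n = len(order_ids)
    B = binarize(project_shared_patients(build_encounter_matrix(billing)), 0.0)
    assert B.physicians == order_ids

    steps = population.hospitals.set_index("hospital_id")["step"]
    primary = np.array(attr.primary)
    step_of = np.array([steps[h] for h in primary])
    volumes = attr.volumes
    shannon = np.array(
        [-(p[p > 0] / s * np.log(p[p > 0] / s)).sum() if (s := p.sum()) > 0 else 0.0
         for p in volumes.astype(float)]
    )
    n_nonprimary = attr.n_nonprimary.astype(float)

    phys = phys.reindex(order_ids)
    X = covariate_frame(phys)
    beta = config.beta
    beta_vec = np.array([getattr(beta, c) for c in COVARIATES])
    fixed_part = (
        beta.intercept
        + X.to_numpy() @ beta_vec
        + beta.shannon * shannon
    )
    modifier = shannon if beta.interaction_var == "shannon" else n_nonprimary

    theta = {
        h: float(rng.normal(0.0, config.tau)) if config.tau > 0 else 0.0
        for h in population.hospitals["hospital_id"]
    }

    same_primary = primary[:, None] == primary[None, :]
    B_wi = np.where(same_primary, B.edges, 0)
    B_ac = B.edges - B_wi
    step_ok = step_of[None, :] <= step_of[:, None]

    # decision sequence: hospitals by (step, id), physicians shuffled within
    sequence: list[int] = []
    hosp_order = sorted(set(primary), key=lambda h: (steps[h], h))
    members = {h: np.flatnonzero(primary == h) for h in hosp_order}
    for h in hosp_order:
        sequence.extend(rng.permutation(members[h]).tolist())

    decided = np.zeros(n, dtype=bool)
    y = np.zeros(n, dtype=float)
    records = []
    for i in sequence:
        wy_wi, flag_wi = _masked_mean(B_wi[i] * decided, y)
        wy_ac, flag_ac = _masked_mean(B_ac[i] * decided * step_ok[i], y)
        wy_wi_pct = 100.0 * wy_wi
        wy_ac_t = float(transform_across(wy_ac))
        lp = (
            fixed_part[i]
            + beta.within * wy_wi_pct
            + (beta.across + beta.across_interaction * modifier[i]) * wy_ac_t
            + theta[primary[i]]
        )
        pi = float(expit(lp))
        y[i] = float(rng.random() < pi)
        decided[i] = True
        records.append(
            {
                "physician_id": order_ids[i],
                "primary_hospital": primary[i],
                "step": int(step_of[i]),
                "wy_wi": wy_wi_pct,
                "wy_wi_undefined": flag_wi,
                "wy_ac": wy_ac,
                "wy_ac_t": wy_ac_t,
                "wy_ac_undefined": flag_ac,
                "shannon": shannon[i],
                "n_nonprimary": n_nonprimary[i],
                "linear_predictor": lp,
                "prob": pi,
            }
        )
    exposures = pd.DataFrame(records).set_index("physician_id").loc[order_ids]
    outcome = pd.Series(y.astype(int), index=pd.Index(order_ids, name="physician_id"),
                        name="participated")
    truth = SimTruth(
        beta=beta,
        tau=config.tau,
        hospital_effects=theta,
        adoption_order=[order_ids[i] for i in sequence],
        true_exposures=exposures,
    )
    return outcome, truth


def simulate_study(config: SimConfig) -> Study:
    """Generate a complete synthetic study (population, billing, outcomes)."""
    population = generate_population(config)
    billing = generate_encounters(population, config)
    outcome, truth = generate_outcomes(population, billing, config)
    physicians = population.physicians.copy()
    physicians["participated"] = (
        outcome.reindex(physicians["physician_id"]).to_numpy().astype(int)
    )
    return Study(physicians, population.hospitals, population.affiliations, billing, truth)
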