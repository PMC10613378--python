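"""Network summary metrics and the hospital-diversity index.

Degree, unnormalized betweenness centrality, network density and per-hospital
subnetwork density summarize the physician network; the Shannon diversity
index ``H_i = -sum_l p_il ln p_il`` (in nats) summarizes how a physician's
encounter volume spreads across hospitals.  A threshold sweep re-binarizes the
weighted network at increasing shared-patient cutoffs and compares the
resulting subnetwork-density distributions to the baseline cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats

from .exceptions import ConfigurationError
from .network import BinaryNetwork, PhysicianAttributions, SharedPatientNetwork, binarize

DEFAULT_CUTOFFS = (1, 10, 50, 100, 500, 1000)


def degree(B: BinaryNetwork) -> pd.Series:
    """Per-physician degree (row sums of ``B``)."""
    return pd.Series(B.edges.sum(axis=1), index=B.physicians, name="degree")


def betweenness(B: BinaryNetwork) -> pd.Series:
    """Unnormalized geodesic betweenness centrality.

    Computed on the full (possibly disconnected) undirected graph; node pairs
    in different components contribute no paths.
    """
    bc = nx.betweenness_centrality(B.to_graph(), normalized=False)
    return pd.Series([bc[p] for p in B.physicians], index=B.physicians, name="betweenness")


def density(B: BinaryNetwork) -> float:
    """Fraction of the ``C(n,2)`` possible edges present; NaN for n < 2."""
    n = B.n
    if n < 2:
        return float("nan")
    return B.n_edges() / (n * (n - 1) / 2)


def split_degree(B: BinaryNetwork, attributions: PhysicianAttributions) -> pd.DataFrame:
    """Total degree split into within- and across-hospital parts.

    Within edges join physicians sharing a primary hospital; across edges join
    physicians with different primary hospitals.  The two parts sum to the
    total degree.
    """
    primary = pd.Series(attributions.primary, index=attributions.physicians)
    prim = primary.reindex(B.physicians).to_numpy()
    same = prim[:, None] == prim[None, :]
    within = (B.edges * same).sum(axis=1)
    total = B.edges.sum(axis=1)
    return pd.DataFrame(
        {
            "degree": total,
            "degree_within": within,
            "degree_across": total - within,
        },
        index=pd.Index(B.physicians, name="physician_id"),
    )


@dataclass
class SubnetworkDensities:
    per_hospital: pd.Series
    excluded: list[str]

    def summary(self) -> dict:
        d = self.per_hospital
        return {
            "mean": float(d.mean()),
            "median": float(d.median()),
            "sd": float(d.std(ddof=1)) if len(d) > 1 else float("nan"),
            "n_hospitals": int(len(d)),
        }


def subnetwork_density(
    B: BinaryNetwork, attributions: PhysicianAttributions
) -> SubnetworkDensities:
    """Edge density of each hospital's primary-attributed physician subgraph.

    Hospitals with fewer than two attributed physicians have no defined
    density and are excluded (and reported).
    """
    primary = pd.Series(attributions.primary, index=attributions.physicians)
    prim = primary.reindex(B.physicians)
    if prim.isna().any():
        missing = prim[prim.isna()].index[0]
        raise ConfigurationError(f"physician '{missing}' has no attribution")
    dens, excluded = {}, []
    for hosp, members in prim.groupby(prim).groups.items():
        idx = [B.physicians.index(p) for p in members]
        m = len(idx)
        if m < 2:
            excluded.append(hosp)
            continue
        sub = B.edges[np.ix_(idx, idx)]
        dens[hosp] = sub.sum() / (m * (m - 1))
    return SubnetworkDensities(
        pd.Series(dens, name="subnetwork_density").sort_index(), excluded
    )


def shannon_diversity(volumes) -> float:
    """Shannon diversity ``H = -sum p ln p`` of a nonnegative volume vector."""
    v = np.asarray(volumes, dtype=float)
    if (v < 0).any():
        raise ConfigurationError("volumes must be nonnegative")
    total = v.sum()
    if total <= 0:
        raise ConfigurationError("physician has no encounters: H undefined")
    p = v[v > 0] / total
    return float(-(p * np.log(p)).sum() + 0.0)


def shannon_diversity_table(attributions: PhysicianAttributions) -> pd.Series:
    """Per-physician Shannon diversity over hospital billing volumes."""
    return pd.Series(
        [shannon_diversity(row) for row in attributions.volumes],
        index=pd.Index(attributions.physicians, name="physician_id"),
        name="shannon",
    )


def metric_table(B: BinaryNetwork, attributions: PhysicianAttributions) -> pd.DataFrame:
    """Per-physician degree (total/within/across), betweenness and diversity."""
    out = split_degree(B, attributions)
    out["betweenness"] = betweenness(B)
    out["shannon"] = shannon_diversity_table(attributions).reindex(out.index)
    return out


def threshold_sweep(
    A: SharedPatientNetwork,
    attributions: PhysicianAttributions,
    cutoffs=DEFAULT_CUTOFFS,
    mode: str = "strict",
) -> pd.DataFrame:
    """Subnetwork-density distributions across shared-patient cutoffs.

    Each cutoff's per-hospital densities are compared to the first (baseline)
    cutoff with a two-sided Mann-Whitney rank test; identical distributions
    yield p = 1.
    """
    cutoffs = list(cutoffs)
    if not cutoffs:
        raise ConfigurationError("cutoffs must be a nonempty list")
    rows = []
    baseline = None
    for cutoff in cutoffs:
        dens = subnetwork_density(binarize(A, cutoff, mode=mode), attributions).per_hospital
        if baseline is None:
            baseline = dens
            p = 1.0
        elif dens.nunique() <= 1 and baseline.nunique() <= 1 and (
            len(dens) and len(baseline) and dens.iloc[0] == baseline.iloc[0]
        ):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(dens, baseline, alternative="two-sided").pvalue)
        rows.append(
            {
                "cutoff": cutoff,
                "mean": float(dens.mean()),
                "median": float(dens.median()),
                "sd": float(dens.std(ddof=1)) if len(dens) > 1 else float("nan"),
                "n_hospitals": len(dens),
                "n_edges": binarize(A, cutoff, mode=mode).n_edges(),
                "p_vs_baseline": p,
            }
        )
    return pd.DataFrame(rows)


def participation_percentage(n_agreed: int, n_invited: int, ndigits: int = 2) -> float:
    """Percentage of invited physicians agreeing to participate."""
    if n_invited <= 0:
        raise ConfigurationError("n_invited must be positive")
    return round(100.0 * n_agreed / n_invited, ndigits)
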