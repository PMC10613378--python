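"""Peer-participation exposures from the decomposed physician network.

The binary network ``B`` splits into a within-hospital part ``B_wi`` (edges
between physicians sharing a primary hospital; block diagonal when nodes are
ordered by hospital) and an across-hospital part ``B_ac`` (everything else).
Row-normalizing either part gives a row-stochastic weight matrix ``W`` whose
product with the binary participation vector ``Y`` is each physician's peer
exposure: the weighted fraction of their peers who participate.

Across-hospital exposures are step-masked: only peers whose primary hospital
was randomized at the same trial step or earlier are eligible, guarding
against reverse causality in the stepped-wedge rollout.  Masking happens
*before* row normalization so weights remain a proper average over eligible
peers.  Rows with no eligible peers are kept (exposure 0) and flagged rather
than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, StructuralError
from .network import BinaryNetwork, PhysicianAttributions
from .metrics import shannon_diversity_table

ACROSS_TRANSFORMS = ("identity", "ln1p-percent", "ln-offset")


@dataclass
class Decomposition:
    """Within/across split of a binary physician network."""

    physicians: list[str]
    B_wi: np.ndarray
    B_ac: np.ndarray
    primary: pd.Series  # physician_id -> primary hospital


@dataclass
class WeightMatrix:
    """Row-stochastic weights; all-zero rows are flagged, not renormalized."""

    W: np.ndarray
    zero_row_flags: np.ndarray


def decompose(B: BinaryNetwork, attributions: PhysicianAttributions) -> Decomposition:
    """Split ``B`` into within- and across-hospital parts (``B_wi + B_ac = B``)."""
    primary = pd.Series(attributions.primary, index=attributions.physicians)
    prim = primary.reindex(B.physicians)
    if prim.isna().any():
        missing = prim[prim.isna()].index[0]
        raise StructuralError(f"physician '{missing}' has no primary-hospital attribution")
    same = prim.to_numpy()[:, None] == prim.to_numpy()[None, :]
    B_wi = np.where(same, B.edges, 0).astype(B.edges.dtype)
    B_ac = B.edges - B_wi
    return Decomposition(list(B.physicians), B_wi, B_ac, prim)


def row_normalize(Bx: np.ndarray) -> WeightMatrix:
    """Divide each row by its sum; zero rows stay zero and are flagged."""
    Bx = np.asarray(Bx, dtype=float)
    if (Bx < 0).any():
        raise ConfigurationError("weight source matrix must be nonnegative")
    sums = Bx.sum(axis=1)
    flags = sums == 0
    safe = np.where(flags, 1.0, sums)
    return WeightMatrix(Bx / safe[:, None], flags)


def within_exposure(W_wi: WeightMatrix, Y) -> tuple[np.ndarray, np.ndarray]:
    """Within-hospital peer participation on a 0-100 scale.

    Returns ``(exposure, flags)`` where flagged physicians (zero within
    degree) get exposure 0.
    """
    y = np.asarray(Y, dtype=float)
    if y.shape[0] != W_wi.W.shape[0]:
        raise StructuralError(
            f"outcome length {y.shape[0]} does not match network size {W_wi.W.shape[0]}"
        )
    return 100.0 * (W_wi.W @ y), W_wi.zero_row_flags.copy()


def step_mask(
    B_ac: np.ndarray,
    primary: pd.Series,
    steps: pd.Series,
) -> np.ndarray:
    """Zero out across-hospital edges to peers at strictly later trial steps."""
    own_step = primary.map(steps)
    if own_step.isna().any():
        hosp = primary[own_step.isna()].iloc[0]
        raise StructuralError(f"hospital '{hosp}' has no trial step assignment")
    s = own_step.to_numpy(dtype=float)
    eligible = s[None, :] <= s[:, None]  # peer j's step <= physician i's step
    return np.where(eligible, B_ac, 0).astype(B_ac.dtype)


def across_exposure(
    B_ac: np.ndarray,
    Y,
    primary: pd.Series,
    steps: pd.Series,
) -> tuple[np.ndarray, np.ndarray]:
    """Step-masked across-hospital peer participation as a proportion in [0, 1].

    The across part of the network is masked to same-step-or-earlier peers
    first, then row-normalized, then multiplied with the outcome vector.
    Physicians with no eligible across peers are flagged with exposure 0.
    """
    masked = step_mask(B_ac, primary, steps)
    W = row_normalize(masked)
    y = np.asarray(Y, dtype=float)
    if y.shape[0] != W.W.shape[0]:
        raise StructuralError("outcome vector does not align with network")
    return W.W @ y, W.zero_row_flags.copy()


def transform_across(
    wy_ac, transform: str = "ln1p-percent", eps: float = 0.5
) -> np.ndarray:
    """Transform the across-exposure proportion for modeling.

    ``ln1p-percent`` (default) maps a proportion p to ``ln(1 + 100 p)``, which
    is monotone, equals 0 at p = 0, and avoids ln(0); ``ln-offset`` uses
    ``ln(100 p + eps)``; ``identity`` returns the percent scale untouched.
    """
    p = np.asarray(wy_ac, dtype=float)
    if transform == "identity":
        return 100.0 * p
    if transform == "ln1p-percent":
        return np.log1p(100.0 * p)
    if transform == "ln-offset":
        return np.log(100.0 * p + eps)
    raise ConfigurationError(
        f"unknown across transform '{transform}' (choose from {ACROSS_TRANSFORMS})"
    )


def build_exposure_table(
    B: BinaryNetwork,
    attributions: PhysicianAttributions,
    Y: pd.Series,
    steps: pd.Series,
    transform: str = "ln1p-percent",
) -> pd.DataFrame:
    """Assemble the per-physician exposure table.

    ``Y`` is a physician_id-indexed binary participation series; ``steps``
    maps hospital_id to trial step.  Columns: within exposure (0-100) and its
    undefined flag, across exposure (proportion) raw and transformed with its
    flag, within/across degree, Shannon diversity and non-primary site count.
    """
    y = Y.reindex(B.physicians)
    if y.isna().any():
        missing = y[y.isna()].index[0]
        raise StructuralError(f"no outcome for physician '{missing}'")
    dec = decompose(B, attributions)
    wy_wi, flag_wi = within_exposure(row_normalize(dec.B_wi), y.to_numpy())
    wy_ac, flag_ac = across_exposure(dec.B_ac, y.to_numpy(), dec.primary, steps)
    shannon = shannon_diversity_table(attributions).reindex(B.physicians)
    nonprim = pd.Series(
        attributions.n_nonprimary, index=attributions.physicians
    ).reindex(B.physicians)
    return pd.DataFrame(
        {
            "wy_wi": wy_wi,
            "wy_wi_undefined": flag_wi,
            "wy_ac": wy_ac,
            "wy_ac_t": transform_across(wy_ac, transform),
            "wy_ac_undefined": flag_ac,
            "degree_within": dec.B_wi.sum(axis=1),
            "degree_across": dec.B_ac.sum(axis=1),
            "shannon": shannon.to_numpy(),
            "n_nonprimary": nonprim.to_numpy(),
        },
        index=pd.Index(B.physicians, name="physician_id"),
    )
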