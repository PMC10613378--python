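"""Construction of patient-sharing networks from physician billing records.

Billing rows (physician_id, patient_id, hospital_id, date) are tallied into a
physician x patient encounter matrix ``Z`` with entries ``z_ik`` (number of
encounters physician *i* billed for patient *k*).  Projecting ``Z`` onto the
physician mode yields the weighted shared-patient adjacency ``A = [a_ij]``:
under the shared-count scheme ``a_ij`` counts the patients seen by both
physicians, under the geometric-mean scheme each shared patient contributes
``sqrt(z_ik * z_jk)``.  A threshold ``a_low`` binarizes ``A`` into ``B``.

The same billing rows also yield per-physician hospital volumes ``V_i``, the
primary hospital ``S_i`` (largest volume, lexicographic tie-break) and the
count of billing hospitals, and a hospital-level network linking two hospitals
whenever a physician billed at both within a time window.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy import sparse

from .exceptions import ConfigurationError, SchemaError, StructuralError

logger = logging.getLogger(__name__)

BILLING_COLUMNS = ("physician_id", "patient_id", "hospital_id", "date")

#: Shared-patient (physician) network window used by the study design.
PHYSICIAN_WINDOW = (dt.date(2019, 1, 1), dt.date(2019, 12, 31))
#: Hospital-network window (pandemic period).
HOSPITAL_WINDOW = (dt.date(2020, 3, 1), dt.date(2021, 5, 31))


def _as_date(value) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


@dataclass(frozen=True)
class Window:
    """Inclusive date window used to filter billing rows."""

    start: dt.date
    end: dt.date

    def __post_init__(self):
        object.__setattr__(self, "start", _as_date(self.start))
        object.__setattr__(self, "end", _as_date(self.end))
        if self.start > self.end:
            raise ConfigurationError(
                f"window: start {self.start} is after end {self.end}"
            )

    def contains(self, dates: pd.Series) -> pd.Series:
        d = pd.to_datetime(dates).dt.date
        return (d >= self.start) & (d <= self.end)


@dataclass
class EncounterMatrix:
    """Physician x patient encounter counts ``z_ik``."""

    physicians: list[str]
    patients: list[str]
    counts: sparse.csr_matrix

    @property
    def empty(self) -> bool:
        return len(self.physicians) == 0

    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class SharedPatientNetwork:
    """Weighted physician adjacency ``A`` (symmetric, zero diagonal)."""

    physicians: list[str]
    weights: np.ndarray
    weight_scheme: str

    def index_of(self, physician_id: str) -> int:
        return self.physicians.index(physician_id)


@dataclass
class BinaryNetwork:
    """Binarized physician adjacency ``B`` at threshold ``a_low``."""

    physicians: list[str]
    edges: np.ndarray
    threshold: float

    @property
    def n(self) -> int:
        return len(self.physicians)

    def n_edges(self) -> int:
        return int(self.edges.sum()) // 2

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.physicians)
        ii, jj = np.nonzero(np.triu(self.edges, k=1))
        g.add_edges_from(
            (self.physicians[i], self.physicians[j]) for i, j in zip(ii, jj)
        )
        return g


@dataclass
class PhysicianAttributions:
    """Per-physician hospital volumes and primary-hospital attribution.

    ``volumes[i, l]`` is physician *i*'s encounter count at hospital *l*;
    ``primary[i]`` is the hospital with the largest volume (ties broken by
    lexicographically smallest hospital id).
    """

    physicians: list[str]
    hospitals: list[str]
    volumes: np.ndarray
    primary: list[str] = field(init=False)

    def __post_init__(self):
        # argmax returns the first (lexicographically smallest) maximizer
        # because hospitals are sorted.
        idx = np.argmax(self.volumes, axis=1)
        self.primary = [self.hospitals[j] for j in idx]

    @property
    def n_sites_total(self) -> np.ndarray:
        """Number of distinct hospitals billed at (``N_i`` total)."""
        return (self.volumes > 0).sum(axis=1)

    @property
    def n_nonprimary(self) -> np.ndarray:
        """Number of non-primary billing hospitals (``N_i``)."""
        return self.n_sites_total - 1

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "physician_id": self.physicians,
                "primary_hospital_id": self.primary,
                "total_encounters": self.volumes.sum(axis=1),
                "n_hospitals": self.n_sites_total,
                "n_nonprimary": self.n_nonprimary,
            }
        )


@dataclass
class HospitalNetwork:
    """Hospital adjacency: entry = physicians billing at both hospitals."""

    hospitals: list[str]
    edges: np.ndarray
    window: Window


def read_billing(path, window: Window | None = None) -> pd.DataFrame:
    """Read a billing table, validating schema and dates.

    Rows outside ``window`` (inclusive) are dropped.  Raises
    :class:`SchemaError` naming any missing column and a row-level error (with
    line number) for unparseable dates.
    """
    df = pd.read_csv(path, dtype=str)
    for col in BILLING_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"billing table is missing column '{col}'")
    dates = pd.to_datetime(df["date"], errors="coerce", format="ISO8601")
    bad = dates.isna() & df["date"].notna()
    if bad.any():
        # +2: header line plus 1-based indexing
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise SchemaError(
            f"billing table line {line}: unparseable date {df['date'].iloc[line - 2]!r}"
        )
    if df["date"].isna().any():
        line = int(np.flatnonzero(df["date"].isna().to_numpy())[0]) + 2
        raise SchemaError(f"billing table line {line}: missing date")
    df = df.assign(date=dates)
    if window is not None:
        df = df.loc[window.contains(df["date"])].reset_index(drop=True)
    logger.info("read_billing: retained %d rows", len(df))
    return df


def _check_records(records: pd.DataFrame):
    for col in ("physician_id", "patient_id", "hospital_id"):
        if col not in records.columns:
            raise SchemaError(f"billing records missing column '{col}'")


def build_encounter_matrix(records: pd.DataFrame) -> EncounterMatrix:
    """Tally billing rows into the encounter matrix ``z_ik``.

    Physicians and patients are ordered lexicographically so the matrix is
    reproducible across runs.  An empty input yields an (explicitly flagged)
    empty matrix.
    """
    _check_records(records)
    if len(records) == 0:
        logger.warning("build_encounter_matrix: empty input, empty matrix returned")
        return EncounterMatrix([], [], sparse.csr_matrix((0, 0), dtype=np.int64))
    physicians = sorted(records["physician_id"].unique())
    patients = sorted(records["patient_id"].unique())
    pi = pd.Categorical(records["physician_id"], categories=physicians).codes
    ki = pd.Categorical(records["patient_id"], categories=patients).codes
    counts = sparse.coo_matrix(
        (np.ones(len(records), dtype=np.int64), (pi, ki)),
        shape=(len(physicians), len(patients)),
    ).tocsr()
    return EncounterMatrix(physicians, patients, counts)


def project_shared_patients(
    Z: EncounterMatrix, scheme: str = "shared-count"
) -> SharedPatientNetwork:
    """Project the encounter matrix onto physicians.

    shared-count: ``a_ij = sum_k I(z_ik>0) I(z_jk>0)``;
    geometric-mean: ``a_ij = sum_k sqrt(z_ik * z_jk)``.
    """
    if scheme == "shared-count":
        zb = (Z.counts > 0).astype(np.int64)
        A = (zb @ zb.T).toarray().astype(float)
    elif scheme == "geometric-mean":
        zs = Z.counts.astype(float)
        zs.data = np.sqrt(zs.data)
        A = (zs @ zs.T).toarray()
    else:
        raise ConfigurationError(f"unknown projection scheme '{scheme}'")
    np.fill_diagonal(A, 0.0)
    return SharedPatientNetwork(list(Z.physicians), A, scheme)


def binarize(
    A: SharedPatientNetwork, a_low: float, mode: str = "strict"
) -> BinaryNetwork:
    """Threshold ``A`` into a binary network.

    ``strict`` applies ``b_ij = I(a_ij > a_low)``; ``inclusive`` applies
    ``b_ij = I(a_ij >= a_low)`` (the "minimum threshold" reading).
    """
    if a_low < 0:
        raise ConfigurationError(f"a_low must be nonnegative, got {a_low}")
    if mode == "strict":
        B = (A.weights > a_low).astype(np.int8)
    elif mode == "inclusive":
        B = (A.weights >= a_low).astype(np.int8)
    else:
        raise ConfigurationError(f"unknown binarize mode '{mode}'")
    np.fill_diagonal(B, 0)
    return BinaryNetwork(list(A.physicians), B, float(a_low))


def attribute_physicians(records: pd.DataFrame) -> PhysicianAttributions:
    """Tally per-physician volumes by hospital and attribute primary hospitals."""
    _check_records(records)
    if len(records) == 0:
        raise StructuralError("cannot attribute physicians from empty records")
    physicians = sorted(records["physician_id"].unique())
    hospitals = sorted(records["hospital_id"].unique())
    pi = pd.Categorical(records["physician_id"], categories=physicians).codes
    hi = pd.Categorical(records["hospital_id"], categories=hospitals).codes
    volumes = np.zeros((len(physicians), len(hospitals)), dtype=np.int64)
    np.add.at(volumes, (pi, hi), 1)
    return PhysicianAttributions(physicians, hospitals, volumes)


def build_hospital_network(
    records: pd.DataFrame, window: Window | None = None
) -> HospitalNetwork:
    """Hospital network: edge weight = physicians billing at both hospitals.

    The default window is the pandemic period used for the hospital-level
    network; pass ``window=None`` after pre-filtering to keep all rows.
    """
    _check_records(records)
    if window is None:
        window = Window(dt.date.min, dt.date.max)
    else:
        records = records.loc[window.contains(records["date"])]
    hospitals = sorted(records["hospital_id"].unique())
    physicians = sorted(records["physician_id"].unique())
    pi = pd.Categorical(records["physician_id"], categories=physicians).codes
    hi = pd.Categorical(records["hospital_id"], categories=hospitals).codes
    presence = np.zeros((len(physicians), len(hospitals)), dtype=np.int64)
    presence[pi, hi] = 1
    edges = presence.T @ presence
    np.fill_diagonal(edges, 0)
    return HospitalNetwork(hospitals, edges, window)


def network_to_graph(nodes: list[str], matrix: np.ndarray) -> nx.Graph:
    """Undirected weighted graph from a symmetric adjacency matrix."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    ii, jj = np.nonzero(np.triu(matrix, k=1))
    g.add_weighted_edges_from(
        (nodes[i], nodes[j], float(matrix[i, j])) for i, j in zip(ii, jj)
    )
    return g


def write_edge_list(nodes: list[str], matrix: np.ndarray, path) -> None:
    """Write a 3-column (source, target, weight) UTF-8 edge list."""
    ii, jj = np.nonzero(np.triu(matrix, k=1))
    pd.DataFrame(
        {
            "source": [nodes[i] for i in ii],
            "target": [nodes[j] for j in jj],
            "weight": matrix[ii, jj],
        }
    ).to_csv(path, index=False)


def write_graphml(nodes: list[str], matrix: np.ndarray, path) -> None:
    nx.write_graphml(network_to_graph(nodes, matrix), path)
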