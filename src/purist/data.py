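"""Domain containers and representation changes.

The purification model works with three representations of an expression
experiment:

* **abundance (intensity) scale** — normalized, non-log-transformed mRNA
  abundance values as delivered by upstream preprocessing
  (:class:`ExpressionMatrix`);
* **count scale** — per-sample integer counts obtained by discretizing a
  tumour abundance matrix; each column is treated as a multinomial draw
  (:class:`CountMatrix`);
* **probability scale** — per-sample distributions over transcripts, used
  for the healthy reference panel and all model parameters
  (:class:`ReferencePanel` and the state containers).

All containers validate their invariants at construction time and freeze
their arrays, so downstream numerical code can assume well-formed input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataError",
    "ExpressionMatrix",
    "CountMatrix",
    "ReferencePanel",
    "ThetaMatrix",
    "CpeState",
    "PpeState",
    "validate_inputs",
    "discretize",
    "to_probability_panel",
    "read_expression",
    "write_matrix",
]

#: tolerance for "sums to one" checks on probability vectors
SIMPLEX_ATOL = 1e-12

#: matrices whose maximum is below this are suspected to be log-scale
LOG_SCALE_CEILING = 30.0


class DataError(ValueError):
    """Invalid or inconsistent input data."""


def _as_id_tuple(ids: Sequence, what: str, expected: int) -> tuple:
    ids = tuple(str(i) for i in ids)
    if len(ids) != expected:
        raise DataError(
            f"{what}: got {len(ids)} identifiers for {expected} rows/columns"
        )
    if len(set(ids)) != len(ids):
        seen, dup = set(), None
        for i in ids:
            if i in seen:
                dup = i
                break
            seen.add(i)
        raise DataError(f"{what}: duplicate identifier {dup!r}")
    return ids


def _first_bad(values: np.ndarray, mask: np.ndarray) -> tuple[int, int]:
    g, s = np.argwhere(mask)[0]
    return int(g), int(s)


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of nonnegative, finite abundance values."""

    values: np.ndarray
    gene_ids: tuple
    sample_ids: tuple

    def __post_init__(self) -> None:
        v = np.array(self.values, dtype=float)
        if v.ndim != 2:
            raise DataError("expression matrix must be 2-dimensional")
        if v.shape[0] < 2:
            raise DataError("need at least 2 genes")
        if v.shape[1] < 1:
            raise DataError("need at least 1 sample")
        self.gene_ids = _as_id_tuple(self.gene_ids, "gene_ids", v.shape[0])
        self.sample_ids = _as_id_tuple(self.sample_ids, "sample_ids", v.shape[1])
        bad = ~np.isfinite(v)
        if bad.any():
            g, s = _first_bad(v, bad)
            raise DataError(
                f"non-finite value at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        neg = v < 0
        if neg.any():
            g, s = _first_bad(v, neg)
            raise DataError(
                f"negative value {v[g, s]} at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        v.setflags(write=False)
        self.values = v

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), tuple(df.index), tuple(df.columns))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.array(self.values), index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    def reindex_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            order = [pos[g] for g in gene_ids]
        except KeyError as e:
            raise DataError(f"gene {e.args[0]!r} absent from matrix") from None
        return ExpressionMatrix(
            self.values[order, :], tuple(gene_ids), self.sample_ids
        )


@dataclass
class CountMatrix:
    """Genes x samples matrix of nonnegative integer counts.

    Column totals act as per-sample multinomial sample sizes, so every
    column must have a positive sum.
    """

    values: np.ndarray
    gene_ids: tuple
    sample_ids: tuple

    def __post_init__(self) -> None:
        v = np.array(self.values)
        if v.ndim != 2:
            raise DataError("count matrix must be 2-dimensional")
        if not np.issubdtype(v.dtype, np.integer):
            f = np.asarray(v, dtype=float)
            if not np.all(np.isfinite(f)) or np.any(f != np.round(f)):
                raise DataError("count matrix entries must be integers")
            v = f.astype(np.int64)
        else:
            v = v.astype(np.int64)
        if np.any(v < 0):
            raise DataError("count matrix entries must be >= 0")
        self.gene_ids = _as_id_tuple(self.gene_ids, "gene_ids", v.shape[0])
        self.sample_ids = _as_id_tuple(self.sample_ids, "sample_ids", v.shape[1])
        colsum = v.sum(axis=0)
        if np.any(colsum == 0):
            s = int(np.argwhere(colsum == 0)[0][0])
            raise DataError(f"sample {self.sample_ids[s]!r} has zero total count")
        v.setflags(write=False)
        self.values = v

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.array(self.values), index=list(self.gene_ids), columns=list(self.sample_ids)
        )


@dataclass
class ReferencePanel:
    """Healthy reference profiles as per-sample probability vectors.

    ``profiles`` holds the matrix B = [b_1 ... b_R], genes along the rows,
    one strictly positive probability column per healthy sample.
    """

    profiles: np.ndarray
    sample_ids: tuple
    gene_ids: tuple

    def __post_init__(self) -> None:
        p = np.array(self.profiles, dtype=float)
        if p.ndim != 2 or p.shape[1] < 1:
            raise DataError("reference panel needs at least one profile column")
        self.gene_ids = _as_id_tuple(self.gene_ids, "gene_ids", p.shape[0])
        self.sample_ids = _as_id_tuple(self.sample_ids, "sample_ids", p.shape[1])
        if np.any(p <= 0):
            raise DataError("reference panel entries must be strictly positive")
        err = np.abs(p.sum(axis=0) - 1.0)
        if np.any(err > SIMPLEX_ATOL):
            s = int(np.argmax(err))
            raise DataError(
                f"reference column {self.sample_ids[s]!r} sums to "
                f"{p[:, s].sum():.17g}, not 1"
            )
        p.setflags(write=False)
        self.profiles = p

    @property
    def n_genes(self) -> int:
        return self.profiles.shape[0]

    @property
    def n_profiles(self) -> int:
        return self.profiles.shape[1]


@dataclass
class ThetaMatrix:
    """Per-sample mixing weights.

    Row n holds the R weights of the healthy reference profiles followed by
    the cancer fraction alpha_n in the last column; every row lies on the
    probability simplex, i.e. the weights and alpha sum to one.
    """

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.array(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[1] < 1:
            raise DataError("theta must be N x (R+1)")
        if np.any(~np.isfinite(w)) or np.any(w < 0) or np.any(w > 1):
            raise DataError("theta entries must lie in [0, 1]")
        err = np.abs(w.sum(axis=1) - 1.0)
        if np.any(err > SIMPLEX_ATOL):
            n = int(np.argmax(err))
            raise DataError(f"theta row {n} sums to {w[n].sum():.17g}, not 1")
        w.setflags(write=False)
        self.weights = w

    @property
    def n_samples(self) -> int:
        return self.weights.shape[0]

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    @property
    def alpha(self) -> np.ndarray:
        """Cancer fractions (last column)."""
        return self.weights[:, -1]


def _check_simplex(p: np.ndarray, what: str) -> np.ndarray:
    p = np.array(p, dtype=float)
    if p.ndim != 1 or np.any(p <= 0):
        raise DataError(f"{what} must be a strictly positive vector")
    if abs(p.sum() - 1.0) > SIMPLEX_ATOL:
        raise DataError(f"{what} sums to {p.sum():.17g}, not 1")
    p.setflags(write=False)
    return p


@dataclass
class CpeState:
    """Parameters of the shared-profile (CPE) stage.

    ``m`` is the shared reference cancer profile, ``nu`` the Dirichlet
    concentration over the mixing weights, ``omega`` the simplex weights
    placing the prior mean of ``m`` inside the convex hull of the healthy
    panel, and ``kappa_prime`` the concentration of that prior.
    """

    theta: ThetaMatrix
    m: np.ndarray
    nu: np.ndarray
    omega: np.ndarray
    kappa_prime: float

    def __post_init__(self) -> None:
        self.m = _check_simplex(self.m, "m")
        nu = np.array(self.nu, dtype=float)
        if nu.ndim != 1 or np.any(nu <= 0):
            raise DataError("nu must be a positive vector")
        if nu.shape[0] != self.theta.n_components:
            raise DataError("nu length must equal theta row length")
        nu.setflags(write=False)
        self.nu = nu
        self.omega = _check_simplex(self.omega, "omega")
        if self.omega.shape[0] != self.theta.n_components - 1:
            raise DataError("omega length must equal the number of references")
        self.kappa_prime = float(self.kappa_prime)
        if not self.kappa_prime > 0:
            raise DataError("kappa_prime must be positive")


@dataclass
class PpeState:
    """Parameters of the per-patient (PPE) stage.

    The cancer fractions (last theta column) are frozen at their CPE
    values and never re-optimized.  ``m``, ``omega`` and ``kappa_prime``
    are carried over from the CPE stage as fixed quantities so the full
    objective remains evaluable.
    """

    cancer_profiles: np.ndarray  # genes x N, one probability column per patient
    kappa_n: np.ndarray
    theta: ThetaMatrix
    nu: np.ndarray
    m: np.ndarray
    omega: np.ndarray
    kappa_prime: float

    def __post_init__(self) -> None:
        c = np.array(self.cancer_profiles, dtype=float)
        if c.ndim != 2:
            raise DataError("cancer_profiles must be genes x patients")
        if np.any(c <= 0):
            raise DataError("cancer profile entries must be strictly positive")
        err = np.abs(c.sum(axis=0) - 1.0)
        if np.any(err > SIMPLEX_ATOL):
            n = int(np.argmax(err))
            raise DataError(f"cancer profile column {n} does not sum to 1")
        c.setflags(write=False)
        self.cancer_profiles = c
        k = np.array(self.kappa_n, dtype=float)
        if k.ndim != 1 or np.any(k <= 0):
            raise DataError("kappa_n must be a positive vector")
        if k.shape[0] != c.shape[1]:
            raise DataError("kappa_n length must equal the number of patients")
        k.setflags(write=False)
        self.kappa_n = k
        nu = np.array(self.nu, dtype=float)
        if nu.ndim != 1 or np.any(nu <= 0):
            raise DataError("nu must be a positive vector")
        nu.setflags(write=False)
        self.nu = nu
        self.m = _check_simplex(self.m, "m")
        self.omega = _check_simplex(self.omega, "omega")
        self.kappa_prime = float(self.kappa_prime)

    @property
    def alpha(self) -> np.ndarray:
        return self.theta.alpha


# ---------------------------------------------------------------------------
# operations


def validate_inputs(
    tumour: ExpressionMatrix, healthy: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Check a tumour/healthy pair for joint consistency.

    The two matrices must describe the same transcript universe.  If the
    gene sets match but the row orderings differ, the healthy matrix is
    re-ordered to the tumour ordering.  If the sets differ, both matrices
    are restricted to the intersection (in tumour order) with a warning;
    a (near-)empty intersection is fatal.  A matrix whose maximum value is
    small enough to suggest log-transformed data triggers a warning, since
    the model requires linear-scale abundances.
    """
    for name, mat in (("tumour", tumour), ("healthy", healthy)):
        if mat.values.max() < LOG_SCALE_CEILING:
            warnings.warn(
                f"{name} matrix maximum {mat.values.max():.3g} is below "
                f"{LOG_SCALE_CEILING:g}; input looks log-transformed, but the "
                "model requires linear-scale abundances",
                UserWarning,
                stacklevel=2,
            )
    t_set, h_set = set(tumour.gene_ids), set(healthy.gene_ids)
    if t_set == h_set:
        if tumour.gene_ids != healthy.gene_ids:
            healthy = healthy.reindex_genes(tumour.gene_ids)
        return tumour, healthy
    shared = [g for g in tumour.gene_ids if g in h_set]
    if len(shared) < 2:
        raise DataError(
            "tumour and healthy matrices share "
            f"{len(shared)} genes; need a common transcript universe"
        )
    warnings.warn(
        f"gene sets differ; restricting both matrices to the {len(shared)} "
        "shared genes",
        UserWarning,
        stacklevel=2,
    )
    return tumour.reindex_genes(shared), healthy.reindex_genes(shared)


def discretize(t: ExpressionMatrix) -> CountMatrix:
    """Round abundances to integer counts, half away from zero.

    Column totals of the result act as per-sample multinomial sample
    sizes; a column that rounds to all zeros is rejected.
    """
    # entries are nonnegative, so floor(x + 0.5) rounds half away from zero
    v = np.floor(t.values + 0.5).astype(np.int64)
    colsum = v.sum(axis=0)
    if np.any(colsum == 0):
        s = int(np.argwhere(colsum == 0)[0][0])
        raise DataError(
            f"sample {t.sample_ids[s]!r} discretizes to an all-zero column"
        )
    return CountMatrix(v, t.gene_ids, t.sample_ids)


def to_probability_panel(
    healthy: ExpressionMatrix, floor: float = 1e-12
) -> ReferencePanel:
    """Normalize healthy profiles into strictly positive probability columns.

    Zero entries are replaced by ``floor`` before normalization so that
    every reference entry stays strictly positive — the model evaluates
    log-densities and cannot tolerate exact zeros in the panel.
    """
    if not floor > 0:
        raise DataError("floor must be positive")
    v = np.array(healthy.values, dtype=float)
    colsum = v.sum(axis=0)
    if np.any(colsum == 0):
        s = int(np.argwhere(colsum == 0)[0][0])
        raise DataError(f"healthy sample {healthy.sample_ids[s]!r} is all zero")
    v[v == 0] = floor
    v /= v.sum(axis=0, keepdims=True)
    return ReferencePanel(v, healthy.sample_ids, healthy.gene_ids)


# ---------------------------------------------------------------------------
# delimited text I/O


def read_expression(path, sep: str = "\t") -> ExpressionMatrix:
    """Read a delimited genes-x-samples matrix.

    First column = transcript identifiers, header row = sample identifiers.
    Missing values are an error: the model has no imputation step.
    """
    # round_trip parsing so written matrices read back bit-identically
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if df.shape[1] < 1:
        raise DataError(f"{path}: no sample columns found")
    if df.isna().to_numpy().any():
        na = np.argwhere(df.isna().to_numpy())[0]
        raise DataError(
            f"{path}: missing value at gene {df.index[na[0]]!r}, "
            f"sample {df.columns[na[1]]!r}"
        )
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as e:
        raise DataError(f"{path}: non-numeric entries ({e})") from None
    return ExpressionMatrix(values, tuple(df.index), tuple(df.columns))


def write_matrix(df: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a matrix with enough digits that reruns are byte-comparable."""
    df.to_csv(path, sep=sep, float_format="%.17g")
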