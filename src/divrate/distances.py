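"""Pairwise sequence distances, alignment variability summaries and the
global molecular-clock likelihood-ratio test.

Distances come in two flavours mirroring the usual below/above-diagonal
table layout: uncorrected p-distances and maximum-likelihood distances
under HKY85 (unequal base frequencies, distinct transition and
transversion rates).  Both use pairwise deletion: any site where either
sequence carries a gap or an ambiguity code is excluded for that pair
only.  Group summaries are arithmetic means over unordered pairs,
reported in percent.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .simulate import hky_rate_matrix

__all__ = [
    "Alignment",
    "AlignmentStats",
    "DistanceMatrix",
    "ClockLRT",
    "read_fasta",
    "write_fasta",
    "p_distance",
    "hky_distance",
    "distance_matrix",
    "group_distance_summary",
    "alignment_stats",
    "clock_lrt",
]

_NUC_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_TRANSITION_PAIRS = {(0, 2), (2, 0), (1, 3), (3, 1)}
MAX_HKY_DISTANCE = 10.0  # beyond this the pair is reported as saturated (nan)


@dataclass(frozen=True)
class Alignment:
    """Equal-length nucleotide rows over ``{A,C,G,T,-,N, IUPAC codes}``."""

    labels: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in length")
        if len(self.rows) < 2:
            raise ValueError("alignment needs >= 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate sequence labels")
        object.__setattr__(self, "rows", [r.upper() for r in self.rows])

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_seqs(self) -> int:
        return len(self.rows)


def read_fasta(path_or_handle) -> Alignment:
    records = list(SeqIO.parse(path_or_handle, "fasta"))
    return Alignment([r.id for r in records], [str(r.seq) for r in records])


def write_fasta(aln: Alignment) -> str:
    out = io.StringIO()
    for label, row in zip(aln.labels, aln.rows):
        out.write(f">{label}\n{row}\n")
    return out.getvalue()


def _comparable(seq_a: str, seq_b: str) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays of both sequences at sites where both are unambiguous."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    a = np.frombuffer(seq_a.upper().encode(), dtype="S1")
    b = np.frombuffer(seq_b.upper().encode(), dtype="S1")
    lut = np.full(256, -1, dtype=np.int8)
    for nuc, idx in _NUC_INDEX.items():
        lut[ord(nuc)] = idx
    ia = lut[a.view(np.uint8)]
    ib = lut[b.view(np.uint8)]
    mask = (ia >= 0) & (ib >= 0)
    return ia[mask].astype(int), ib[mask].astype(int)


def p_distance(seq_a: str, seq_b: str) -> float:
    """Proportion of mismatches among pairwise-comparable sites."""
    ia, ib = _comparable(seq_a, seq_b)
    if len(ia) == 0:
        raise ValueError("no comparable sites between the two sequences")
    return float(np.mean(ia != ib))


def _pair_counts(ia: np.ndarray, ib: np.ndarray) -> np.ndarray:
    """Symmetrized 4x4 site-pattern count matrix."""
    N = np.zeros((4, 4))
    np.add.at(N, (ia, ib), 1.0)
    return N


def hky_distance(
    seq_a: str,
    seq_b: str,
    kappa: float | None = None,
    base_freqs=None,
) -> float:
    """Maximum-likelihood pairwise distance under HKY85.

    Base frequencies default to the empirical frequencies of the pair;
    the transition/transversion parameter ``kappa`` is estimated jointly
    with the distance unless fixed.  Distance is expected substitutions
    per site.  Saturated pairs (optimum beyond ``MAX_HKY_DISTANCE``)
    return ``nan`` rather than a fabricated number.
    """
    ia, ib = _comparable(seq_a, seq_b)
    m = len(ia)
    if m == 0:
        raise ValueError("no comparable sites between the two sequences")
    if np.all(ia == ib):
        return 0.0
    N = _pair_counts(ia, ib)
    if base_freqs is None:
        counts = N.sum(axis=1) + N.sum(axis=0)
        pi = counts / counts.sum()
    else:
        pi = np.asarray(base_freqs, dtype=float)
    pi = np.clip(pi, 1e-10, None)
    pi /= pi.sum()

    def neg_loglik(d: float, kap: float) -> float:
        Q = hky_rate_matrix(kap, pi)
        w, V = np.linalg.eig(Q)
        P = np.real(V @ np.diag(np.exp(w * d)) @ np.linalg.inv(V))
        P = np.clip(P, 1e-300, None)
        joint = pi[:, None] * P
        return -float(np.sum(N * np.log(joint)))

    p = float(np.mean(ia != ib))

    def profile(kap: float) -> tuple[float, float]:
        res = minimize_scalar(
            lambda d: neg_loglik(d, kap),
            bounds=(1e-9, MAX_HKY_DISTANCE),
            method="bounded",
            options={"xatol": 1e-10},
        )
        return float(res.fun), float(res.x)

    if kappa is not None:
        _, d_hat = profile(kappa)
    else:
        res = minimize_scalar(
            lambda lk: profile(np.exp(lk))[0],
            bounds=(np.log(0.05), np.log(100.0)),
            method="bounded",
            options={"xatol": 1e-8},
        )
        _, d_hat = profile(float(np.exp(res.x)))
    if d_hat >= MAX_HKY_DISTANCE * (1.0 - 1e-6):
        return float("nan")
    return d_hat


@dataclass(frozen=True)
class AlignmentStats:
    """Variable-site and parsimony-informative counts."""

    n_sites: int
    variable_sites: int
    parsimony_informative: int

    @property
    def pct_pi(self) -> float:
        return 100.0 * self.parsimony_informative / self.n_sites

    def __post_init__(self) -> None:
        if not (self.parsimony_informative <= self.variable_sites <= self.n_sites):
            raise ValueError("PI <= variable <= n_sites violated")


def alignment_stats(aln: Alignment) -> AlignmentStats:
    """Variable = column with >= 2 distinct unambiguous states; PI =
    column with >= 2 states each carried by >= 2 sequences."""
    arr = np.array([list(r) for r in aln.rows])
    variable = 0
    pi_count = 0
    for j in range(aln.length):
        col = arr[:, j]
        states, counts = np.unique(
            col[np.isin(col, list(_NUC_INDEX))], return_counts=True
        )
        if len(states) >= 2:
            variable += 1
            if np.count_nonzero(counts >= 2) >= 2:
                pi_count += 1
    return AlignmentStats(aln.length, variable, pi_count)


@dataclass
class DistanceMatrix:
    """Pairwise uncorrected and HKY ML distances with group summaries.

    ``uncorrected`` plays the below-diagonal role and ``model_corrected``
    the above-diagonal role of the conventional combined table; both are
    stored as full symmetric matrices (proportions, not percent).
    """

    labels: list[str]
    uncorrected: np.ndarray
    model_corrected: np.ndarray
    group_assignment: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.labels)
        for mat in (self.uncorrected, self.model_corrected):
            if mat.shape != (n, n):
                raise ValueError("matrix shape does not match labels")
            if not np.allclose(np.diag(mat), 0.0):
                raise ValueError("distance diagonals must be 0")

    def to_table_tsv(self) -> str:
        """Combined layout: uncorrected below the diagonal, model-corrected
        above, in percent to 2 decimals; within-group mean columns appended."""
        summary = group_distance_summary(self)
        header = ["taxon"] + [str(i + 1) for i in range(len(self.labels))]
        header += ["Within Group unco", "Within Group HKY"]
        lines = ["\t".join(header)]

        def fmt(v: float) -> str:
            return "" if np.isnan(v) else f"{100.0 * v:.2f}"

        for i, lab in enumerate(self.labels):
            cells = [lab]
            for j in range(len(self.labels)):
                if i == j:
                    cells.append("")
                elif j > i:
                    cells.append(fmt(self.model_corrected[i, j]))
                else:
                    cells.append(fmt(self.uncorrected[i, j]))
            group = self.group_assignment.get(lab)
            within = summary["within"].get(group, {}) if group else {}
            cells.append(
                "" if within.get("uncorrected") is None else f"{within['uncorrected']:.2f}"
            )
            cells.append(
                "" if within.get("model_corrected") is None else f"{within['model_corrected']:.2f}"
            )
            lines.append("\t".join(cells))
        return "\n".join(lines) + "\n"


def distance_matrix(
    aln: Alignment,
    group_assignment: dict[str, str] | None = None,
    kappa: float | None = None,
) -> DistanceMatrix:
    """All pairwise p-distances and HKY ML distances for an alignment."""
    n = aln.n_seqs
    unco = np.zeros((n, n))
    hky = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            unco[i, j] = unco[j, i] = p_distance(aln.rows[i], aln.rows[j])
            hky[i, j] = hky[j, i] = hky_distance(aln.rows[i], aln.rows[j], kappa=kappa)
    return DistanceMatrix(
        labels=list(aln.labels),
        uncorrected=unco,
        model_corrected=hky,
        group_assignment=dict(group_assignment or {}),
    )


def group_distance_summary(dm: DistanceMatrix) -> dict:
    """Within- and between-group mean distances over unordered pairs, in
    percent.  Singleton groups get ``None`` within-means (undefined, not
    zero); saturated (nan) model distances are excluded from means."""
    groups: dict[str, list[int]] = {}
    for idx, lab in enumerate(dm.labels):
        g = dm.group_assignment.get(lab)
        if g is not None:
            groups.setdefault(g, []).append(idx)

    def pair_mean(mat: np.ndarray, idx_a, idx_b, within: bool):
        vals = []
        if within:
            vals = [
                mat[i, j]
                for k, i in enumerate(idx_a)
                for j in idx_a[k + 1 :]
            ]
        else:
            vals = [mat[i, j] for i in idx_a for j in idx_b]
        vals = [v for v in vals if not np.isnan(v)]
        return 100.0 * float(np.mean(vals)) if vals else None

    within = {
        g: {
            "uncorrected": pair_mean(dm.uncorrected, idx, None, True),
            "model_corrected": pair_mean(dm.model_corrected, idx, None, True),
        }
        for g, idx in groups.items()
    }
    between = {}
    names = sorted(groups)
    for a_i, ga in enumerate(names):
        for gb in names[a_i + 1 :]:
            between[(ga, gb)] = {
                "uncorrected": pair_mean(dm.uncorrected, groups[ga], groups[gb], False),
                "model_corrected": pair_mean(
                    dm.model_corrected, groups[ga], groups[gb], False
                ),
            }
    return {"within": within, "between": between}


@dataclass(frozen=True)
class ClockLRT:
    """Likelihood-ratio test of a global molecular clock.

    Consumes externally computed tree log-likelihoods with the clock
    enforced (null) and not enforced (alternative); the degrees of
    freedom must be supplied (n-2 for a rooted clock comparison of n
    sequences under the usual parameterization, but tools differ, so no
    default is assumed).
    """

    lnl_clock: float
    lnl_free: float
    df: int

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError("df must be >= 1")
        if self.lnl_free < self.lnl_clock:
            raise ValueError(
                "clock (constrained) likelihood exceeds the unconstrained one; "
                "the models are nested, so this indicates an input error"
            )

    @property
    def statistic(self) -> float:
        return 2.0 * (self.lnl_free - self.lnl_clock)

    @property
    def p_value(self) -> float:
        return float(chi2.sf(self.statistic, self.df))


def clock_lrt(lnl_clock: float, lnl_free: float, df: int) -> ClockLRT:
    return ClockLRT(lnl_clock, lnl_free, df)
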