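"""Exact contingency-table tests for cytoplasmic association analyses.

The null model conditions on both margins: every r x c table T with the
observed row and column sums has multivariate hypergeometric probability

    P(T) = (prod_i r_i!  prod_j c_j!) / (N! prod_ij n_ij!)

and the two-sided p-value is the total probability of tables no more probable
than the observed one (probability-mass ordering, the Fisher-Freeman-Halton
generalization; ties included).  Small problems are solved by exhaustive
enumeration of margin-fixed tables; when the enumeration exceeds a configurable
cap the test falls back to independent Monte Carlo sampling of margin-fixed
tables (Patefield's algorithm via :func:`scipy.stats.random_table`) with a
mandatory seed, reporting the (k+1)/(m+1) estimate and its binomial standard
error.  Probabilities are compared on the log scale with a relative tie
tolerance of 1e-7.

The linkage-disequilibrium test for two haploid loci (one allele per locus per
specimen, as for markers co-transmitted on the same cytoplasm) is the same
exact test applied to the allele x allele table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import random_table

__all__ = [
    "SpecimenRecord",
    "ContingencyTable",
    "ExactTestResult",
    "build_table",
    "fisher_exact",
    "ld_test",
    "count_incongruent",
]

#: log-scale tie tolerance: a table counts toward the tail when
#: log P(T) <= log P(obs) + LOG_TIE_EPS.
LOG_TIE_EPS = 1e-7

DEFAULT_ENUMERATION_CAP = 1_000_000
DEFAULT_MC_REPS = 100_000

_MISSING_TOKENS = (None, "", ".", "ND", "NA")


@dataclass(frozen=True)
class SpecimenRecord:
    """One typed specimen joined to its cytoplasmic and host annotations."""

    specimen_id: str
    population_id: str | None = None
    taxon: str | None = None
    wpip_group: str | None = None
    wpip_haplotype: str | None = None
    mtdna_group: str | None = None
    mtdna_haplotype: str | None = None
    ank2: str | None = None
    pk1: str | None = None
    gp15: str | None = None
    mutl: str | None = None
    repa: str | None = None

    def __post_init__(self) -> None:
        annotations = (
            self.taxon, self.wpip_group, self.mtdna_group,
            self.mtdna_haplotype, self.ank2, self.pk1,
        )
        if all(a in _MISSING_TOKENS for a in annotations):
            raise ValueError(
                f"specimen {self.specimen_id!r}: every annotation is missing"
            )


@dataclass(frozen=True)
class ContingencyTable:
    row_labels: tuple
    col_labels: tuple
    counts: np.ndarray  # (r, c) non-negative ints

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape must match labels")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)
        df.loc["Total"] = df.sum()
        df["Total"] = df.sum(axis=1)
        return df

    def __str__(self) -> str:
        return self.to_frame().to_string()


@dataclass(frozen=True)
class ExactTestResult:
    p_value: float
    method: str  # enumeration | monte_carlo
    n_tables_or_reps: int
    mc_standard_error: float | None = None
    seed: int | None = None
    warnings: tuple = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if self.method == "enumeration" and self.seed is not None:
            raise ValueError("enumeration results carry no seed")


def build_table(
    records, row_factor: str, col_factor: str, drop_missing: bool = True
) -> ContingencyTable:
    """Cross-tabulate two annotation factors over specimen records."""
    rows, cols = [], []
    for rec in records:
        r = getattr(rec, row_factor)
        c = getattr(rec, col_factor)
        if drop_missing and (r in _MISSING_TOKENS or c in _MISSING_TOKENS):
            continue
        rows.append("." if r in _MISSING_TOKENS else r)
        cols.append("." if c in _MISSING_TOKENS else c)
    if not rows:
        raise ValueError(
            f"no records left for {row_factor} x {col_factor} after filtering"
        )
    ct = pd.crosstab(pd.Series(rows, name=row_factor), pd.Series(cols, name=col_factor))
    return ContingencyTable(
        tuple(ct.index), tuple(ct.columns), ct.to_numpy()
    )


# ---------------------------------------------------------------------------
# exact test

def _log_prob_const(row_margins, col_margins):
    n = row_margins.sum()
    return (
        gammaln(row_margins + 1).sum()
        + gammaln(col_margins + 1).sum()
        - gammaln(n + 1)
    )


def _log_prob(counts, const):
    return const - gammaln(np.asarray(counts) + 1).sum()


def _enumerate_tables(row_margins, col_margins, cap):
    """Yield every non-negative integer matrix with the given margins.

    Cells are filled row-major; the last column and last row are forced.  Cell
    bounds prune infeasible branches.  Raises OverflowError past *cap* tables.
    """
    r, c = len(row_margins), len(col_margins)
    table = np.zeros((r, c), dtype=np.int64)
    produced = 0

    def rec(i, col_rem):
        nonlocal produced
        if i == r - 1:
            if all(cr >= 0 for cr in col_rem):
                table[r - 1, :] = col_rem
                produced += 1
                if produced > cap:
                    raise OverflowError("enumeration cap exceeded")
                yield table
            return
        yield from rec_row(i, 0, row_margins[i], col_rem)

    def rec_row(i, j, row_rem, col_rem):
        if j == c - 1:
            if 0 <= row_rem <= col_rem[j]:
                table[i, j] = row_rem
                new_col = list(col_rem)
                new_col[j] -= row_rem
                yield from rec(i + 1, new_col)
            return
        rest_cols = sum(col_rem[j + 1:])
        lo = max(0, row_rem - rest_cols)
        hi = min(row_rem, col_rem[j])
        for v in range(lo, hi + 1):
            table[i, j] = v
            new_col = list(col_rem)
            new_col[j] -= v
            yield from rec_row(i, j + 1, row_rem - v, new_col)

    yield from rec(0, list(col_margins))


def enumerate_log_probs(table: ContingencyTable, cap=DEFAULT_ENUMERATION_CAP):
    """Log-probability of every margin-fixed table (diagnostic / oracle path)."""
    const = _log_prob_const(table.row_margins, table.col_margins)
    return np.array(
        [
            _log_prob(t, const)
            for t in _enumerate_tables(table.row_margins, table.col_margins, cap)
        ]
    )


def _trim(table: ContingencyTable) -> ContingencyTable:
    keep_r = table.counts.sum(axis=1) > 0
    keep_c = table.counts.sum(axis=0) > 0
    return ContingencyTable(
        tuple(l for l, k in zip(table.row_labels, keep_r) if k),
        tuple(l for l, k in zip(table.col_labels, keep_c) if k),
        table.counts[np.ix_(keep_r, keep_c)],
    )


def fisher_exact(
    table: ContingencyTable,
    enumeration_cap: int = DEFAULT_ENUMERATION_CAP,
    mc_reps: int = DEFAULT_MC_REPS,
    seed: int | None = None,
) -> ExactTestResult:
    """Two-sided exact test of independence on an r x c table.

    Enumeration when the margin-fixed table count fits under
    ``enumeration_cap``, otherwise seeded Monte Carlo (``seed`` then required).
    A table degenerate to a single row or column yields p = 1 with a warning.
    """
    table = _trim(table)
    r, c = table.counts.shape
    if r < 2 or c < 2:
        msg = "degenerate table (single non-zero row or column): p = 1"
        warnings.warn(msg, stacklevel=2)
        return ExactTestResult(1.0, "enumeration", 1, warnings=(msg,))

    rows, cols = table.row_margins, table.col_margins
    const = _log_prob_const(rows, cols)
    lp_obs = _log_prob(table.counts, const)

    try:
        tail = 0.0
        count = 0
        for t in _enumerate_tables(rows, cols, enumeration_cap):
            lp = _log_prob(t, const)
            count += 1
            if lp <= lp_obs + LOG_TIE_EPS:
                tail += np.exp(lp)
        return ExactTestResult(min(tail, 1.0), "enumeration", count)
    except OverflowError:
        pass

    if seed is None:
        raise ValueError(
            "enumeration cap exceeded and no seed supplied for Monte Carlo"
        )
    rng = np.random.default_rng(seed)
    dist = random_table(rows, cols)
    hits = 0
    done = 0
    block = 20_000
    while done < mc_reps:
        m = min(block, mc_reps - done)
        samples = dist.rvs(m, method="patefield", random_state=rng)
        samples = np.asarray(samples).reshape(m, r, c)
        lps = const - gammaln(samples + 1).sum(axis=(1, 2))
        hits += int((lps <= lp_obs + LOG_TIE_EPS).sum())
        done += m
    p_hat = (hits + 1.0) / (mc_reps + 1.0)
    se = float(np.sqrt(p_hat * (1.0 - p_hat) / mc_reps))
    return ExactTestResult(p_hat, "monte_carlo", mc_reps, mc_standard_error=se, seed=seed)


def ld_test(
    records,
    locus_a: str = "ank2",
    locus_b: str = "pk1",
    **test_kwargs,
) -> ExactTestResult:
    """Exact test of linkage disequilibrium between two haploid loci.

    Builds the allele x allele table (one allele per locus per specimen) and
    delegates to :func:`fisher_exact`.  A locus fixed for a single allele is
    degenerate: p = 1.
    """
    table = build_table(records, locus_a, locus_b, drop_missing=True)
    return fisher_exact(table, **test_kwargs)


def count_incongruent(table: ContingencyTable) -> list:
    """Per-row off-modal counts of a wPip x mtDNA (or similar) table.

    For each row the modal column is the argmax cell; the off-modal count is
    the row total minus the modal cell.  Ties report every modal candidate and
    set ``tie=True``.
    """
    if table.counts.size == 0:
        raise ValueError("empty table")
    out = []
    for i, label in enumerate(table.row_labels):
        row = table.counts[i]
        m = int(row.max())
        modal = [table.col_labels[j] for j in range(len(row)) if row[j] == m]
        off_cells = {
            table.col_labels[j]: int(row[j])
            for j in range(len(row))
            if row[j] > 0 and table.col_labels[j] not in modal[:1]
        }
        out.append(
            {
                "row": label,
                "total": int(row.sum()),
                "modal": modal if len(modal) > 1 else modal[0],
                "modal_count": m,
                "off_modal": int(row.sum()) - m,
                "off_modal_cells": off_cells,
                "tie": len(modal) > 1,
            }
        )
    return out
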