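"""Tissue-enrichment filtering of replicate RNA-seq abundance matrices.

The analysis compares two sample groups — group ``A`` (the tissue of
interest, e.g. dissected planarian auricles) against group ``B`` (whole
bodies) — on a genes x samples abundance matrix. Counts are converted to
TPM (transcripts per million: counts are divided by effective transcript
length and rescaled so every sample sums to one million), genes with
negligible cumulative abundance are removed, a per-gene two-sided Welch
t-test on log2(TPM + pseudocount) scores differential abundance, and the
enriched set is the intersection of three filters: cumulative TPM at or
above a floor, p-value at or below a cap, and fold-change (ratio of group
mean TPM) at or above a floor.

The differential test here is a deliberately simple, reproducible
stand-in for proprietary RNA-seq differential-expression machinery: a
Welch (unequal-variance) t-test on log2-transformed TPM. Raw p-values are
used for filtering by default; an optional Benjamini–Hochberg mode is
provided for users who want FDR control instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DegenerateInputError, ParameterError

__all__ = [
    "ExpressionStudy",
    "GeneSet",
    "compute_tpm",
    "abundance_filter",
    "differential_test",
    "select_enriched",
    "DE_COLUMNS",
]

#: Columns of the differential-expression table returned by
#: :func:`differential_test` (one row per gene, indexed by gene ID).
DE_COLUMNS = (
    "mean_tpm_A",
    "mean_tpm_B",
    "cumulative_tpm",
    "fold_change",
    "p_value",
    "passed_abundance",
)


@dataclass
class ExpressionStudy:
    """A genes x samples abundance matrix with a two-group sample design.

    Parameters
    ----------
    values
        Non-negative matrix, rows indexed by unique gene IDs, columns by
        sample names. Units are raw counts or TPM depending on
        ``value_kind``.
    sample_groups
        Map from sample name to group label, ``"A"`` (tissue) or ``"B"``
        (body). Every column of ``values`` must be present.
    lengths
        Per-gene effective length in bases (> 0), required to compute TPM
        from counts; may be omitted when ``values`` is already TPM.
    value_kind
        Either ``"counts"`` or ``"tpm"``.
    """

    values: pd.DataFrame
    sample_groups: Mapping[str, str]
    lengths: pd.Series | None = None
    value_kind: str = "counts"

    def __post_init__(self) -> None:
        if self.value_kind not in ("counts", "tpm"):
            raise ParameterError(f"value_kind must be 'counts' or 'tpm', got {self.value_kind!r}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ConfigurationError(f"duplicate gene IDs: {dupes[:5]}")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise DegenerateInputError("abundance matrix contains non-finite values")
        if (arr < 0).any():
            raise DegenerateInputError("abundance matrix contains negative values")
        missing = [s for s in self.values.columns if s not in self.sample_groups]
        if missing:
            raise ConfigurationError(f"samples without a group label: {missing}")
        bad = {s: g for s, g in self.sample_groups.items() if g not in ("A", "B")}
        if bad:
            raise ConfigurationError(f"group labels must be 'A' or 'B': {bad}")
        for grp in ("A", "B"):
            if not self.samples_in_group(grp):
                raise ConfigurationError(f"no samples assigned to group {grp}")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.values.index)
            if self.lengths.isna().any():
                missing_len = self.lengths.index[self.lengths.isna()].tolist()
                raise ConfigurationError(f"genes without a length: {missing_len[:5]}")
            if (self.lengths <= 0).any():
                raise ConfigurationError("gene lengths must be > 0")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_groups[s] == group]


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers for one species, with provenance."""

    species_label: str
    ids: frozenset[str]
    provenance: str = ""
    thresholds: dict = field(default_factory=dict, compare=False)

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, gene: str) -> bool:
        return gene in self.ids


def compute_tpm(study: ExpressionStudy) -> ExpressionStudy:
    """Convert a count matrix to TPM.

    For gene *g* with count :math:`c_g` and effective length :math:`L_g`
    in one sample, :math:`\\mathrm{TPM}_g = 10^6 (c_g/L_g) / \\sum_h c_h/L_h`.
    Every sample column of the result sums to :math:`10^6`.

    Raises
    ------
    ConfigurationError
        If the study carries no gene lengths.
    DegenerateInputError
        If a sample has zero total count (TPM undefined); the message
        names the sample.
    """
    if study.value_kind != "counts":
        raise ParameterError("compute_tpm expects value_kind='counts'")
    if study.lengths is None:
        raise ConfigurationError("gene lengths are required to compute TPM from counts")
    rate = study.values.div(study.lengths, axis=0)
    colsum = rate.sum(axis=0)
    zero = colsum.index[colsum == 0].tolist()
    if zero:
        raise DegenerateInputError(f"sample(s) with zero total abundance: {zero}")
    tpm = rate.div(colsum, axis=1) * 1e6
    return replace(study, values=tpm, value_kind="tpm")


def abundance_filter(study: ExpressionStudy, min_cumulative_tpm: float = 0.1) -> GeneSet:
    """Retain genes whose TPM summed across *all* samples reaches a floor.

    A gene is removed when its cumulative TPM is strictly below
    ``min_cumulative_tpm`` (default 0.1); the boundary value itself is
    retained.
    """
    if study.value_kind != "tpm":
        raise ParameterError("abundance_filter expects value_kind='tpm'")
    if min_cumulative_tpm < 0:
        raise ParameterError(f"min_cumulative_tpm must be >= 0, got {min_cumulative_tpm}")
    cumulative = study.values.sum(axis=1)
    kept = cumulative.index[cumulative >= min_cumulative_tpm]
    return GeneSet(
        species_label="A",
        ids=frozenset(kept),
        provenance=f"cumulative TPM >= {min_cumulative_tpm} across {study.values.shape[1]} samples",
        thresholds={"min_cumulative_tpm": min_cumulative_tpm},
    )


def _ttest(
    a: np.ndarray, b: np.ndarray, var_floor: float, pooled: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised two-sided two-sample t-test across rows (genes).

    ``pooled=True`` is the Student test (pooled variance, df =
    n_A + n_B - 2); ``pooled=False`` the Welch test (Welch–Satterthwaite
    df). At equal group sizes the two statistics coincide and only the
    degrees of freedom differ; the pooled df keeps the type-I error at
    its nominal level for the tiny replicate numbers typical here,
    whereas the Welch approximation is conservative at n = 3 per group.

    Group variances are floored at ``var_floor`` so genes with zero
    within-group variance remain testable: equal means give t = 0
    (p = 1), unequal means a very large |t| (p near 0), preserving the
    ordering of evidence. A single-sample group contributes the floor as
    its variance and, for Welch, drops out of the df sum.
    """
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1) if na > 1 else np.zeros(a.shape[0])
    vb = b.var(axis=1, ddof=1) if nb > 1 else np.zeros(b.shape[0])
    va = np.maximum(va, var_floor)
    vb = np.maximum(vb, var_floor)
    if pooled:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        sp2 = np.maximum(sp2, var_floor)
        se2 = sp2 * (1.0 / na + 1.0 / nb)
        df = np.full_like(se2, float(na + nb - 2))
    else:
        se2 = va / na + vb / nb
        denom = np.zeros_like(se2)
        if na > 1:
            denom += (va / na) ** 2 / (na - 1)
        if nb > 1:
            denom += (vb / nb) ** 2 / (nb - 1)
        df = se2**2 / denom
    t = (ma - mb) / np.sqrt(se2)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, np.minimum(p, 1.0)


def differential_test(
    study: ExpressionStudy,
    log_pseudocount: float = 1.0,
    fc_pseudocount: float = 0.01,
    min_cumulative_tpm: float = 0.1,
    var_floor: float = 1e-8,
    test: str = "student",
    adjust: str = "none",
) -> pd.DataFrame:
    """Per-gene differential abundance between group A and group B.

    Returns a DataFrame (columns :data:`DE_COLUMNS`, one row per gene):
    group mean TPMs, cumulative TPM over all samples, fold-change
    ``(mean_A + fc_pseudocount) / (mean_B + fc_pseudocount)``, a two-sided
    t-test p-value computed on ``log2(TPM + log_pseudocount)``, and a
    ``passed_abundance`` flag (cumulative TPM >= ``min_cumulative_tpm``).
    ``test`` selects the pooled-variance Student test (default; exact
    type-I level at equal group sizes) or the Welch unequal-variance
    test (``"welch"``, conservative at very small n).

    The abundance flag is computed here, before selection, so both the
    pre- and post-filter gene counts are available downstream. With
    ``adjust="bh"`` p-values are Benjamini–Hochberg adjusted (not part of
    the default filtering contract, which uses raw p-values).

    Raises
    ------
    DegenerateInputError
        If both groups have fewer than two samples (no variance
        estimate is possible).
    """
    if study.value_kind != "tpm":
        raise ParameterError("differential_test expects value_kind='tpm'")
    if adjust not in ("none", "bh"):
        raise ParameterError(f"adjust must be 'none' or 'bh', got {adjust!r}")
    if test not in ("student", "welch"):
        raise ParameterError(f"test must be 'student' or 'welch', got {test!r}")
    samples_a = study.samples_in_group("A")
    samples_b = study.samples_in_group("B")
    if len(samples_a) < 2 and len(samples_b) < 2:
        raise DegenerateInputError(
            "differential test needs at least 2 samples in one group "
            f"(got {len(samples_a)} in A, {len(samples_b)} in B)"
        )
    va = study.values[samples_a].to_numpy(dtype=float)
    vb = study.values[samples_b].to_numpy(dtype=float)
    mean_a = va.mean(axis=1)
    mean_b = vb.mean(axis=1)
    cumulative = study.values.sum(axis=1).to_numpy(dtype=float)

    num = mean_a + fc_pseudocount
    den = mean_b + fc_pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(den > 0, num / den, np.where(num > 0, np.inf, 1.0))

    la = np.log2(va + log_pseudocount)
    lb = np.log2(vb + log_pseudocount)
    _, p = _ttest(la, lb, var_floor, pooled=(test == "student"))
    if adjust == "bh":
        p = stats.false_discovery_control(p, method="bh")

    return pd.DataFrame(
        {
            "mean_tpm_A": mean_a,
            "mean_tpm_B": mean_b,
            "cumulative_tpm": cumulative,
            "fold_change": fold,
            "p_value": p,
            "passed_abundance": cumulative >= min_cumulative_tpm,
        },
        index=study.gene_ids,
    )


def select_enriched(
    de: pd.DataFrame,
    min_fold: float = 5.0,
    max_p: float = 0.05,
    min_cumulative_tpm: float | None = None,
    species_label: str = "A",
) -> GeneSet:
    """Select the tissue-enriched gene set from a differential table.

    A gene is included when it passed the abundance floor AND
    ``p_value <= max_p`` AND ``fold_change >= min_fold`` — all three
    boundaries inclusive. With the default ``min_cumulative_tpm=None``
    the ``passed_abundance`` flag recorded by :func:`differential_test`
    is used; passing an explicit value re-derives the flag from
    ``cumulative_tpm``. Lowering ``min_fold`` to 2 yields the broader
    differentially-expressed regime.
    """
    if min_fold < 0:
        raise ParameterError(f"min_fold must be >= 0, got {min_fold}")
    if not 0 <= max_p <= 1:
        raise ParameterError(f"max_p must be in [0, 1], got {max_p}")
    if min_cumulative_tpm is None:
        abundant = de["passed_abundance"].to_numpy(bool)
        tpm_thr: float | str = "as flagged"
    else:
        abundant = (de["cumulative_tpm"] >= min_cumulative_tpm).to_numpy(bool)
        tpm_thr = min_cumulative_tpm
    mask = abundant & (de["p_value"] <= max_p) & (de["fold_change"] >= min_fold)
    ids = frozenset(de.index[mask])
    return GeneSet(
        species_label=species_label,
        ids=ids,
        provenance=(
            f"fold_change >= {min_fold}, p <= {max_p}, cumulative TPM filter: {tpm_thr}; "
            f"{len(ids)} of {len(de)} genes"
        ),
        thresholds={
            "min_fold": min_fold,
            "max_p": max_p,
            "min_cumulative_tpm": tpm_thr,
        },
    )
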