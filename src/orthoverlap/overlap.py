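"""Monte Carlo significance test for gene-set overlap in orthogroup space.

The question: a universe of N single-copy orthogroups contains K marked
ones (orthogroups of the target set, e.g. genes whose expression depends
on a transcription factor in species B). A second set of n orthogroups
(the projection of the tissue-enriched genes of species A) overlaps the
marked ones in k_obs orthogroups. Is k_obs larger than chance?

The null model is sampling without replacement: each of B iterations
draws n distinct orthogroups uniformly from the N and records how many
are marked. The enrichment p-value is estimated two ways —

* ``p_mc_raw``       = exceedances / B, where an exceedance is a null
  iteration with overlap >= k_obs;
* ``p_mc_corrected`` = (exceedances + 1) / (B + 1), the add-one
  estimator, which is never exactly zero and is the headline value
  (with 0 exceedances in 10,000 iterations it reports ~1e-4, the
  resolution of the simulation, rather than an impossible p = 0).

The null overlap distribution is exactly hypergeometric(N, K, n), so the
analytic upper tail :func:`hypergeom_upper_tail` serves as an oracle for
the simulation; it is reported alongside the Monte Carlo estimates.

Sampling uses random keys: each iteration assigns an iid uniform key to
every universe item and takes the n smallest, an exactly uniform draw of
an n-subset. Iterations are vectorised in chunks, so B = 10,000 at
N ~ 8,700 runs in about a second on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .errors import ParameterError

__all__ = [
    "OverlapTestResult",
    "monte_carlo_overlap",
    "hypergeom_upper_tail",
    "overlap_report",
    "parse_report",
]

REPORT_SCHEMA_VERSION = 1


@dataclass
class OverlapTestResult:
    """Full record of one Monte Carlo overlap test."""

    N: int  #: universe size (number of single-copy orthogroups)
    K: int  #: marked (target) orthogroups in the universe
    n: int  #: drawn (enriched-projection) orthogroups
    k_obs: int  #: observed overlap
    B: int  #: number of null iterations
    seed: int
    alternative: str  #: "greater" (enrichment) or "less" (depletion)
    exceedances: int  #: null iterations at least as extreme as k_obs
    max_null: int  #: largest null overlap seen
    p_mc_raw: float
    p_mc_corrected: float
    p_exact: float  #: analytic hypergeometric tail
    null_histogram: np.ndarray  #: counts of each null overlap 0..min(K, n)

    def __post_init__(self) -> None:
        self.null_histogram = np.asarray(self.null_histogram, dtype=np.int64)


def _validate(N: int, K: int, n: int, k: int, *, k_name: str = "k_obs") -> None:
    if N < 0:
        raise ParameterError(f"N must be >= 0, got N={N}")
    if not 0 <= K <= N:
        raise ParameterError(f"K must be in [0, N={N}], got K={K}")
    if not 0 <= n <= N:
        raise ParameterError(f"n must be in [0, N={N}], got n={n}")
    if not 0 <= k <= min(K, n):
        raise ParameterError(
            f"{k_name} must be in [0, min(K, n)={min(K, n)}], got {k_name}={k}"
        )


def _sample_null_overlaps(
    N: int, K: int, n: int, B: int, rng: np.random.Generator, chunk: int = 256
) -> np.ndarray:
    """Draw B null overlap counts by uniform n-subset sampling.

    Marked items occupy indices 0..K-1 of the universe; an iteration's
    overlap is the number of its n sampled indices below K. The n-subset
    is the argpartition of iid uniform keys, chunked to cap memory at
    ``chunk * N`` floats.
    """
    if n == 0 or N == 0:
        return np.zeros(B, dtype=np.int64)
    out = np.empty(B, dtype=np.int64)
    done = 0
    while done < B:
        m = min(chunk, B - done)
        keys = rng.random((m, N))
        if n < N:
            sub = np.argpartition(keys, n, axis=1)[:, :n]
        else:
            sub = np.broadcast_to(np.arange(N), (m, N))
        out[done : done + m] = (sub < K).sum(axis=1)
        done += m
    return out


def monte_carlo_overlap(
    N: int,
    K: int,
    n: int,
    k_obs: int,
    B: int = 10_000,
    seed: int = 0,
    alternative: str = "greater",
) -> OverlapTestResult:
    """Monte Carlo overlap test under the without-replacement null.

    Parameters
    ----------
    N, K, n, k_obs
        Universe size, marked-set size, drawn-set size, observed overlap.
    B
        Number of null iterations (>= 1).
    seed
        Seed for the pseudo-random generator; identical seeds give
        identical results.
    alternative
        ``"greater"`` tests enrichment (exceedance = null overlap >=
        k_obs); ``"less"`` tests depletion (null overlap <= k_obs).
    """
    _validate(N, K, n, k_obs)
    if B < 1:
        raise ParameterError(f"B must be >= 1, got B={B}")
    if alternative not in ("greater", "less"):
        raise ParameterError(f"alternative must be 'greater' or 'less', got {alternative!r}")
    rng = np.random.default_rng(seed)
    overlaps = _sample_null_overlaps(N, K, n, B, rng)
    if alternative == "greater":
        exceedances = int((overlaps >= k_obs).sum())
        p_exact = hypergeom_upper_tail(k_obs, N, K, n)
    else:
        exceedances = int((overlaps <= k_obs).sum())
        p_exact = float(stats.hypergeom.cdf(k_obs, N, K, n))
    hist = np.bincount(overlaps, minlength=min(K, n) + 1)
    return OverlapTestResult(
        N=N,
        K=K,
        n=n,
        k_obs=k_obs,
        B=B,
        seed=seed,
        alternative=alternative,
        exceedances=exceedances,
        max_null=int(overlaps.max(initial=0)),
        p_mc_raw=exceedances / B,
        p_mc_corrected=(exceedances + 1) / (B + 1),
        p_exact=p_exact,
        null_histogram=hist,
    )


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """Exact P(X >= k) for X ~ hypergeometric(N, K, n).

    The analytic oracle for :func:`monte_carlo_overlap`. ``k <= 0``
    returns 1; ``k > min(K, n)`` returns 0 (overlap that large is
    impossible). Evaluated via the survival function, which works in
    log space internally and stays accurate deep in the tail.
    """
    _validate(N, K, n, max(min(k, min(K, n)), 0), k_name="k")
    if k <= 0:
        return 1.0
    if k > min(K, n):
        return 0.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def overlap_report(
    result: OverlapTestResult,
    labels: dict[str, str] | None = None,
    gene_pairs: list[tuple[str, str, str]] | None = None,
) -> dict:
    """JSON-serialisable report of an overlap test.

    ``labels`` may name the universe/target/enriched sets;
    ``gene_pairs`` lists (orthogroup, gene_A, gene_B) for the overlapping
    orthogroups when gene-level inputs were available.
    """
    d = asdict(result)
    d["null_histogram"] = result.null_histogram.tolist()
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "test": d,
        "labels": labels or {},
    }
    if gene_pairs is not None:
        report["overlap_gene_pairs"] = [list(p) for p in gene_pairs]
    return report


def parse_report(report: dict) -> OverlapTestResult:
    """Reconstruct an :class:`OverlapTestResult` from its report dict."""
    if report.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise ParameterError(
            f"unsupported report schema_version {report.get('schema_version')!r}"
        )
    return OverlapTestResult(**report["test"])
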