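"""Alien-index screening of transcripts for contamination.

Each assembled transcript is BLASTed against a mixed database whose
subjects are labelled either *ingroup* (taxa related to the assembled
species — here Platyhelminthes) or *outgroup* (everything else: other
animals, non-metazoan eukaryotes, bacteria, archaea). Two per-query
summaries flag candidate contaminants or horizontal transfers:

* ``outgroup_best`` — the single best hit (smallest e-value) is to an
  outgroup subject;
* the alien index, AI = ln(best ingroup E + floor) - ln(best outgroup E
  + floor), positive when the outgroup hit is stronger, with transcripts
  flagged when AI strictly exceeds a cutoff (default 40).

A query with no hit in a group gets the no-hit sentinel e-value 1, so a
transcript with only ingroup hits has a strongly negative AI. The floor
(default 1e-200) keeps logarithms finite when BLAST reports an e-value
of exactly 0. Flagged transcripts are reported, not removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InputFormatError

__all__ = [
    "BLAST_OUTFMT6_COLUMNS",
    "ContaminationSummary",
    "read_blast_outfmt6",
    "read_group_map",
    "label_hits",
    "best_hits",
    "alien_index",
    "screen",
    "contamination_summary",
]

#: Column names of BLAST tabular output with default ``-outfmt 6``.
BLAST_OUTFMT6_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)

NO_HIT_EVALUE = 1.0
DEFAULT_FLOOR = 1e-200
DEFAULT_CUTOFF = 40.0


def read_blast_outfmt6(path: str | Path) -> pd.DataFrame:
    """Read a BLAST ``-outfmt 6`` tabular report."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=BLAST_OUTFMT6_COLUMNS,
        dtype={"qseqid": str, "sseqid": str},
        comment="#",
    )
    if (df["evalue"] < 0).any():
        bad = df.loc[df["evalue"] < 0, "qseqid"].iloc[0]
        raise InputFormatError(f"negative e-value for query {bad!r}")
    return df


def read_group_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping subject ID -> {ingroup, outgroup}."""
    groups: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 2 or fields[1] not in ("ingroup", "outgroup"):
            raise InputFormatError(f"bad subject-group line: {line!r}")
        groups[fields[0]] = fields[1]
    return groups


def label_hits(hits: pd.DataFrame, group_map: dict[str, str]) -> pd.DataFrame:
    """Attach the subject_group column; unknown subjects are an error."""
    grp = hits["sseqid"].map(group_map)
    if grp.isna().any():
        unknown = hits.loc[grp.isna(), "sseqid"].unique()[:5].tolist()
        raise InputFormatError(f"subjects without a group label: {unknown}")
    out = hits.copy()
    out["subject_group"] = grp
    return out


def best_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Per-query minimum e-value per subject group.

    Expects a labelled hit table (``label_hits``). Returns a DataFrame
    indexed by query ID with columns ``best_e_ingroup`` and
    ``best_e_outgroup``; a group with no hit gets the sentinel e-value 1.
    """
    if (hits["evalue"] < 0).any():
        raise InputFormatError("negative e-value in hit table")
    pivot = hits.pivot_table(
        index="qseqid", columns="subject_group", values="evalue", aggfunc="min"
    )
    out = pd.DataFrame(index=pivot.index)
    for grp in ("ingroup", "outgroup"):
        col = pivot[grp] if grp in pivot.columns else pd.Series(np.nan, index=pivot.index)
        out[f"best_e_{grp}"] = col.fillna(NO_HIT_EVALUE)
    out.index.name = "qseqid"
    return out


def alien_index(
    best_e_ingroup, best_e_outgroup, floor: float = DEFAULT_FLOOR
):
    """AI = ln(best ingroup E + floor) - ln(best outgroup E + floor).

    Antisymmetric in its arguments; positive when the outgroup hit is
    stronger (smaller e-value). Accepts scalars or arrays.
    """
    e_in = np.asarray(best_e_ingroup, dtype=float)
    e_out = np.asarray(best_e_outgroup, dtype=float)
    ai = np.log(e_in + floor) - np.log(e_out + floor)
    return float(ai) if ai.ndim == 0 else ai


def screen(
    hits: pd.DataFrame,
    all_queries=None,
    cutoff: float = DEFAULT_CUTOFF,
    floor: float = DEFAULT_FLOOR,
) -> pd.DataFrame:
    """Per-query alien-index records from a labelled hit table.

    Returns a DataFrame indexed by query with ``best_e_ingroup``,
    ``best_e_outgroup``, ``ai``, ``outgroup_best`` (best overall hit is
    outgroup; ties count as ingroup) and ``flagged`` (AI strictly above
    ``cutoff``). ``all_queries`` may list screened query IDs that
    produced no hits at all; they enter the table with both sentinels,
    AI = 0, and are never flagged.
    """
    rec = best_hits(hits)
    if all_queries is not None:
        rec = rec.reindex(pd.Index(pd.unique(pd.Series(list(all_queries)))).union(rec.index))
        rec = rec.fillna(NO_HIT_EVALUE)
    rec = rec.sort_index()
    rec["ai"] = alien_index(rec["best_e_ingroup"], rec["best_e_outgroup"], floor)
    rec["outgroup_best"] = rec["best_e_outgroup"] < rec["best_e_ingroup"]
    rec["flagged"] = rec["ai"] > cutoff
    return rec


@dataclass(frozen=True)
class ContaminationSummary:
    n_queries: int
    n_outgroup_best: int
    n_flagged: int
    cutoff: float

    @property
    def frac_outgroup_best(self) -> float:
        return self.n_outgroup_best / self.n_queries

    @property
    def frac_flagged(self) -> float:
        return self.n_flagged / self.n_queries


def contamination_summary(records: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF) -> ContaminationSummary:
    """Fractions of screened queries that are outgroup-best / AI-flagged.

    The denominator is every screened query, including those without any
    hit. Flagging is strict: AI exactly equal to the cutoff passes.
    """
    if len(records) == 0:
        raise DegenerateInputError("contamination summary of zero queries")
    flagged = records["ai"] > cutoff
    return ContaminationSummary(
        n_queries=len(records),
        n_outgroup_best=int(records["outgroup_best"].sum()),
        n_flagged=int(flagged.sum()),
        cutoff=cutoff,
    )
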