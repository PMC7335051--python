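"""Monoclonality calls from per-read CDR3 annotations.

A unique CDR3 peptide marks one B-cell clone (VDJ rearrangement happens in
vivo, before line establishment). Reads are filtered on annotation quality,
singleton clonotypes removed, and each surviving clonotype's representativity
(percent of retained reads) drives the verdict: two or more clonotypes at
>= 20% make the sample polyclonal; otherwise a major clone at >= 80% makes it
monoclonal; anything else is inconclusive. Technical replicates are
reconciled by discarding clonotypes seen at >= 20% in only one replicate
(amplicon contamination signature).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "J_MOTIF",
    "ClonotypeTable",
    "ClonalityCall",
    "filter_cdr3",
    "representativity",
    "classify",
    "reconcile_replicates",
    "call_sample",
]

#: Conserved CDR3/FR4 Phe/Trp-Gly-X-Gly motif expected in the J region.
J_MOTIF = re.compile(r"[FW]G.G")

MIN_CDR3_LENGTH = 5
REPRESENTATIVITY_THRESHOLD = 20.0  # percent, inclusive
MONOCLONAL_THRESHOLD = 80.0  # percent, inclusive

_REQUIRED = ["cdr3_peptide", "cdr3_found", "vdj_frame", "top_d_gene", "j_region_aa"]
_NA = {"N/A", "", "NA", None}


@dataclass
class ClonotypeTable:
    """Read counts and representativity (percent of retained reads) per clone."""

    counts: pd.Series  # index: cdr3 peptide

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())

    @property
    def representativity(self) -> pd.Series:
        return 100.0 * self.counts / self.counts.sum()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"reads": self.counts, "representativity_pct": self.representativity}
        ).sort_values("reads", ascending=False)


@dataclass
class ClonalityCall:
    verdict: str  # monoclonal | polyclonal | inconclusive
    major_clone: str | None
    sequences_over_20pct: list[str]
    suspect_clones: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


def filter_cdr3(records: pd.DataFrame) -> pd.DataFrame:
    """Apply the read-level quality filters, then drop singleton clonotypes.

    Record-level conditions: CDR3 found, VDJ frame present, top D gene
    present, CDR3 length >= 5 aa, and the [FW]-G-X-G motif present in the
    J-region translation. Clonotypes covered by a single retained read are
    then removed. Idempotent.
    """
    missing = [c for c in _REQUIRED if c not in records.columns]
    if missing:
        raise ValueError(f"read table missing columns: {missing}")
    df = records
    found = df["cdr3_found"].astype(str).str.upper()
    keep = (
        ~found.isin({"FALSE", "NOT_FOUND", "0"})
        & ~df["vdj_frame"].isin(_NA)
        & df["vdj_frame"].notna()
        & ~df["top_d_gene"].isin(_NA)
        & df["top_d_gene"].notna()
        & (df["cdr3_peptide"].astype(str).str.len() >= MIN_CDR3_LENGTH)
        & df["j_region_aa"].astype(str).str.contains(J_MOTIF)
    )
    df = df.loc[keep]
    clone_counts = df["cdr3_peptide"].value_counts()
    singletons = clone_counts[clone_counts == 1].index
    return df[~df["cdr3_peptide"].isin(singletons)].reset_index(drop=True)


def representativity(records: pd.DataFrame) -> ClonotypeTable:
    """Count reads per unique CDR3 peptide among filtered records."""
    if len(records) == 0:
        raise ValueError("no retained reads")
    return ClonotypeTable(counts=records["cdr3_peptide"].value_counts())


def classify(table: ClonotypeTable) -> ClonalityCall:
    """Apply the 20%/80% representativity rules (thresholds inclusive).

    Polyclonality (>= 2 clonotypes at >= 20%) is checked before the
    monoclonal rule, following the printed rule order.
    """
    rep = table.representativity
    over = rep[rep >= REPRESENTATIVITY_THRESHOLD]
    major = rep.idxmax() if len(rep) else None
    if len(over) >= 2:
        return ClonalityCall(
            verdict="polyclonal", major_clone=major,
            sequences_over_20pct=list(over.index),
        )
    if major is not None and rep[major] >= MONOCLONAL_THRESHOLD:
        return ClonalityCall(
            verdict="monoclonal", major_clone=major,
            sequences_over_20pct=list(over.index),
        )
    return ClonalityCall(
        verdict="inconclusive", major_clone=major,
        sequences_over_20pct=list(over.index),
    )


def reconcile_replicates(
    call_a: ClonalityCall,
    call_b: ClonalityCall,
    table_a: ClonotypeTable,
    table_b: ClonotypeTable,
) -> ClonalityCall:
    """Consensus verdict over two technical replicates.

    A clonotype reaching 20% in only one replicate is flagged suspect
    (likely amplicon contamination) and excluded; the consensus is then
    recomputed on the concordant clonotypes' pooled counts. If the two
    replicate verdicts disagree even after exclusion, the consensus is
    inconclusive with both calls reported.
    """
    over_a = set(call_a.sequences_over_20pct)
    over_b = set(call_b.sequences_over_20pct)
    suspects = sorted(over_a ^ over_b)
    concordant = sorted(over_a & over_b)

    counts = (
        table_a.counts.reindex(
            table_a.counts.index.union(table_b.counts.index), fill_value=0
        )
        + table_b.counts.reindex(
            table_a.counts.index.union(table_b.counts.index), fill_value=0
        )
    )
    counts = counts.drop(index=[s for s in suspects if s in counts.index])
    flags = [f"suspect:{s}" for s in suspects]
    if counts.sum() == 0:
        return ClonalityCall(
            verdict="inconclusive", major_clone=None, sequences_over_20pct=[],
            suspect_clones=suspects, flags=flags + ["no concordant reads"],
        )
    consensus = classify(ClonotypeTable(counts=counts))

    # replicate-level verdicts recomputed without the suspect clones
    def _reverdict(table: ClonotypeTable) -> str:
        kept = table.counts.drop(index=[s for s in suspects if s in table.counts.index])
        if kept.sum() == 0:
            return "inconclusive"
        return classify(ClonotypeTable(counts=kept)).verdict

    va, vb = _reverdict(table_a), _reverdict(table_b)
    if va != vb:
        return ClonalityCall(
            verdict="inconclusive",
            major_clone=consensus.major_clone,
            sequences_over_20pct=consensus.sequences_over_20pct,
            suspect_clones=suspects,
            flags=flags + [f"replicate verdicts disagree: {va} vs {vb}"],
        )
    consensus.suspect_clones = suspects
    consensus.flags = flags
    return consensus


def call_sample(reads: pd.DataFrame) -> tuple[ClonalityCall, dict[str, ClonotypeTable]]:
    """Filter, tabulate and classify one sample's reads, replicate-aware.

    With two replicates the calls are reconciled; a single replicate is
    passed through flagged ``unreplicated``; more than two replicates are
    reconciled pairwise against the first (rare; flagged).
    """
    tables: dict[str, ClonotypeTable] = {}
    calls: dict[str, ClonalityCall] = {}
    reps = (
        list(dict.fromkeys(reads["replicate"])) if "replicate" in reads.columns else ["r1"]
    )
    for rep in reps:
        sub = reads[reads["replicate"] == rep] if "replicate" in reads.columns else reads
        filtered = filter_cdr3(sub)
        if len(filtered) == 0:
            continue
        tables[rep] = representativity(filtered)
        calls[rep] = classify(tables[rep])
    if not calls:
        return (
            ClonalityCall("inconclusive", None, [], flags=["no retained reads"]),
            tables,
        )
    reps = list(calls)
    if len(reps) == 1:
        call = calls[reps[0]]
        call.flags.append("unreplicated")
        return call, tables
    call = reconcile_replicates(calls[reps[0]], calls[reps[1]], tables[reps[0]], tables[reps[1]])
    if len(reps) > 2:
        call.flags.append(f"only first two of {len(reps)} replicates reconciled")
    return call, tables
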