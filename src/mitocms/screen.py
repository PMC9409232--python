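"""Candidate CMS gene screen: integrate uniqueness, chimera, TM and expression.

The screen mirrors how sterility candidates are triaged in comparative
mitogenome studies: an ORF is interesting when it exists only in the
sterile cytoplasm (UR), has a chimeric known-gene/unknown structure (CM)
and its product carries a transmembrane segment (TM).  Tier 1 requires all
three, tier 2 drops the TM requirement, tier 3 keeps only uniqueness.
Expression evidence (upregulation in the sterile line) ranks candidates
within a tier but never promotes a non-unique ORF.  Protein-coding genes
that are weakly expressed and show intron retention are reported separately
as splicing-defect candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .chimeras import ChimeraDecomposition, match_orfs
from .hydropathy import TmSegment
from .orfs import OrfRecord


@dataclass
class OrfEvidence:
    orf_id: str
    aa_length: int
    unique_to_cms: bool
    chimeric: bool
    has_tm: bool
    upregulated_in_cms: bool | None  # None when no expression data
    tier: int | None                 # 1, 2, 3 or None

    @staticmethod
    def assign_tier(ur: bool, cm: bool, tm: bool) -> int | None:
        if ur and cm and tm:
            return 1
        if ur and cm:
            return 2
        if ur:
            return 3
        return None


@dataclass
class CandidateReport:
    rows: list[OrfEvidence]
    venn_counts: dict
    splicing_defect_candidates: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"orf_id": r.orf_id, "aa_length": r.aa_length, "unique": r.unique_to_cms,
                 "chimeric": r.chimeric, "tm": r.has_tm,
                 "upregulated": r.upregulated_in_cms, "tier": r.tier}
                for r in self.rows
            ]
        )


def venn_counts(all_orfs: set, ur: set, cm: set, tm: set) -> dict:
    """Sizes of the four ORF classes and their intersections."""
    return {
        "all": len(all_orfs),
        "UR": len(ur), "CM": len(cm), "TM": len(tm),
        "UR&CM": len(ur & cm), "UR&TM": len(ur & tm), "CM&TM": len(cm & tm),
        "UR&CM&TM": len(ur & cm & tm),
    }


def screen(orfs_cms: list[OrfRecord], orfs_restorer: list[OrfRecord],
           decompositions: dict[str, ChimeraDecomposition],
           tm_results: dict[str, list[TmSegment]],
           de_results: pd.DataFrame | None = None,
           retention_notes: list[dict] | None = None,
           match_kwargs: dict | None = None) -> CandidateReport:
    """Build the tiered candidate report for the CMS-line ORF set.

    ``decompositions`` and ``tm_results`` are keyed by CMS-line orf_id; ids
    present there but absent from the ORF set are an error.  ``de_results``
    (optional) is the differential-expression frame indexed by gene/ORF id.
    """
    orf_ids = {o.orf_id for o in orfs_cms}
    for key in list(decompositions) + list(tm_results):
        if key not in orf_ids:
            raise KeyError(f"evidence for unknown ORF {key!r}")

    matches = match_orfs(orfs_restorer, orfs_cms, **(match_kwargs or {}))
    ur_ids = {o.orf_id for o in matches["uniqueB"]}
    cm_ids = {oid for oid, d in decompositions.items() if d.is_chimeric}
    tm_ids = {oid for oid, segs in tm_results.items() if segs}

    rows = []
    for o in orfs_cms:
        ur = o.orf_id in ur_ids
        cm = o.orf_id in cm_ids
        tm = o.orf_id in tm_ids
        up: bool | None = None
        if de_results is not None and o.orf_id in de_results.index:
            rec = de_results.loc[o.orf_id]
            up = bool(rec["significant"] and rec["log2FC"] > 0)
        rows.append(
            OrfEvidence(o.orf_id, o.aa_length, ur, cm, tm, up,
                        OrfEvidence.assign_tier(ur, cm, tm))
        )
    rows.sort(
        key=lambda r: (
            r.tier if r.tier is not None else 99,
            0 if r.upregulated_in_cms else 1,
            -r.aa_length,
            r.orf_id,
        )
    )
    vc = venn_counts({o.orf_id for o in orfs_cms}, ur_ids, cm_ids, tm_ids)
    return CandidateReport(rows, vc, retention_notes or [])
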