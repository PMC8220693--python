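"""Criterion (iv): literature-evidence classification of candidate ASVs.

Candidates surviving the statistical filters are judged by their
taxonomy: membership of the genus/family in a published contaminant
blocklist (taxa recurrently found in laboratory reagents) versus
documented evidence that the taxon is a human commensal or pathogen.
Each ASV falls in exactly one of six categories crossing blocklist
membership with evidence status; "likely contaminant" (blocklisted, no
evidence) and "no evidence" (classifiable at family/genus but unknown to
the commensal/pathogen literature) are discarded, everything else —
including ASVs resolvable only above family level, which may represent
novel organisms — is retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .tables import RANKS, TaxonomyTable

USABLE_RANKS = ("genus", "family")

CATEGORIES = (
    "likely contaminant",            # blocklisted, no commensal/pathogen evidence
    "blocklisted with evidence",     # blocklisted but documented commensal/pathogen
    "blocklisted uncharacterised",   # blocklisted lineage, unusable rank resolution
    "commensal or pathogen",         # off-list, documented evidence
    "no evidence",                   # off-list, usable rank, no evidence found
    "uncharacterised",               # off-list, resolvable only above family
)

DISCARD = frozenset({"likely contaminant", "no evidence"})


def _normalise(name: str) -> str:
    """Case-fold and strip bracketed synonym markers, e.g. '[Clostridium]'."""
    return name.strip().strip("[]").lower()


@dataclass
class EvidenceLists:
    """Blocklist and commensal/pathogen evidence taxa, keyed by rank."""

    blocklist: set[tuple[str, str]]            # (rank, normalised name)
    commensal_evidence: set[tuple[str, str]]   # (rank, normalised name)

    @classmethod
    def from_frames(cls, blocklist: pd.DataFrame, evidence: pd.DataFrame) -> "EvidenceLists":
        def build(df: pd.DataFrame) -> set[tuple[str, str]]:
            out = set()
            for _, row in df.iterrows():
                name, rank = str(row["name"]), str(row["rank"]).lower()
                if not name:
                    raise ValueError("empty taxon name in evidence list")
                if rank not in RANKS:
                    raise ValueError(f"unknown rank {rank!r} in evidence list")
                out.add((rank, _normalise(name)))
            return out

        return cls(build(blocklist), build(evidence))

    @classmethod
    def from_tsv(cls, blocklist_path, evidence_path) -> "EvidenceLists":
        return cls.from_frames(
            pd.read_csv(blocklist_path, sep="\t", dtype=str),
            pd.read_csv(evidence_path, sep="\t", dtype=str),
        )


def consensus_taxonomy(lineage_a: TaxonomyTable, lineage_b: TaxonomyTable) -> TaxonomyTable:
    """Consensus of two classifications: the deepest agreeing rank prefix.

    Agreement is case-insensitive with bracketed synonyms normalised; the
    first disagreement truncates the lineage at the last agreeing rank.
    """
    if set(lineage_a.frame.index) != set(lineage_b.frame.index):
        raise ValueError("taxonomy tables cover different ASV sets")
    records = []
    for asv in lineage_a.frame.index:
        consensus = {}
        for rank in RANKS:
            va = lineage_a.rank_value(asv, rank)
            vb = lineage_b.rank_value(asv, rank)
            if va and vb and _normalise(va) == _normalise(vb):
                consensus[rank] = va
            else:
                break
        records.append({"asv_id": asv, **consensus})
    return TaxonomyTable(pd.DataFrame(records))


def assign_category(lineage: dict | tuple, lists: EvidenceLists) -> str:
    """Classify one lineage into its evidence category.

    ``lineage`` maps rank -> name (or is an ordered tuple over the
    standard ranks).  Matching is exact on normalised names, at genus
    first then family.
    """
    if not isinstance(lineage, dict):
        lineage = dict(zip(RANKS, lineage))
    entries = {(r, _normalise(v)) for r, v in lineage.items() if v}
    blocked = bool(entries & lists.blocklist)
    evidenced = bool(entries & lists.commensal_evidence)
    usable = any(lineage.get(r, "") for r in USABLE_RANKS)
    if blocked:
        if evidenced:
            return "blocklisted with evidence"
        if usable:
            return "likely contaminant"
        return "blocklisted uncharacterised"
    if evidenced:
        return "commensal or pathogen"
    if usable:
        return "no evidence"
    return "uncharacterised"


def categorise_asvs(tax: TaxonomyTable, asv_ids, lists: EvidenceLists) -> pd.Series:
    """Evidence category per candidate ASV (exactly one each)."""
    cats = {}
    for asv in asv_ids:
        lineage = {r: tax.rank_value(asv, r) for r in RANKS}
        cats[asv] = assign_category(lineage, lists)
    return pd.Series(cats, name="category")


def criterion_iv_filter(asv_ids, categories: pd.Series) -> list:
    """Retain candidates whose category is not a discard category,
    preserving input order."""
    return [a for a in asv_ids if categories[a] not in DISCARD]
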