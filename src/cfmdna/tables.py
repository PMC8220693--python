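"""Core data containers and preprocessing for ASV count tables.

The pipeline operates on three aligned objects: an ASV-by-sample count
table, a per-sample study design (sample type plus the technical factors
that drive batch effects), and a per-ASV taxonomy.  All downstream
statistics consume these containers, so validation happens here, once.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SAMPLE_TYPES = frozenset(
    {
        "plasma",
        "stool",
        "saliva",
        "plasma_denc",
        "stool_denc",
        "saliva_denc",
        "ntc",
        "mock",
    }
)

#: sample_type of the matched DNA-extraction negative control for each
#: biological sample type.
DENC_OF = {"plasma": "plasma_denc", "stool": "stool_denc", "saliva": "saliva_denc"}

RANKS = ("domain", "phylum", "class", "order", "family", "genus")


class ValidationError(ValueError):
    """Raised when an input table violates a structural contract."""


@dataclass
class AsvCountTable:
    """Non-negative integer ASV x sample matrix with aligned identifiers.

    Parameters
    ----------
    counts
        DataFrame with ASV ids as the index and sample ids as columns.
        Values must be non-negative integers (sequencing read counts).
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            raise ValidationError("duplicate ASV ids")
        if df.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        if df.shape[1] == 0:
            raise ValidationError("no samples")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("non-numeric counts")
        if np.any(~np.isfinite(values.astype(float))):
            raise ValidationError("non-finite counts")
        if np.any(values < 0):
            raise ValidationError("negative counts")
        if not np.allclose(values, np.round(values.astype(float))):
            raise ValidationError("non-integer counts")
        df = df.astype(np.int64)
        df.index.name = None
        df.columns.name = None
        self.counts = df

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.counts.to_numpy()

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids) -> "AsvCountTable":
        return AsvCountTable(self.counts.loc[:, list(sample_ids)])

    def subset_asvs(self, asv_ids) -> "AsvCountTable":
        return AsvCountTable(self.counts.loc[list(asv_ids)])

    def drop_empty_asvs(self) -> "AsvCountTable":
        keep = self.counts.sum(axis=1) > 0
        if not keep.all() and not keep.any():
            warnings.warn("no ASVs with positive counts remain")
        return AsvCountTable(self.counts.loc[keep])


@dataclass
class StudyDesign:
    """Per-sample factors: sample type, patient and technical variables.

    The technical factors form a nesting hierarchy: extraction day within
    extraction batch within sequencing run.  ``replicate_group`` links
    re-extractions of the same biological sample across two batches.
    """

    frame: pd.DataFrame

    REQUIRED = ("sample_id", "sample_type")
    OPTIONAL = (
        "patient_id",
        "sequencing_run",
        "extraction_batch",
        "extraction_day",
        "replicate_group",
    )

    def __post_init__(self) -> None:
        df = self.frame
        if "sample_id" in df.columns:
            df = df.set_index("sample_id")
        if df.index.has_duplicates:
            raise ValidationError("duplicate sample ids in design")
        if "sample_type" not in df.columns:
            raise ValidationError("design lacks a sample_type column")
        bad = set(df["sample_type"]) - SAMPLE_TYPES
        if bad:
            raise ValidationError(f"unknown sample_type tokens: {sorted(bad)}")
        for col in self.OPTIONAL:
            if col not in df.columns:
                df[col] = pd.NA
        self.frame = df
        self._check_nesting("extraction_day", "extraction_batch")
        self._check_nesting("extraction_batch", "sequencing_run")
        self._check_replicate_groups()

    def _check_nesting(self, inner: str, outer: str) -> None:
        sub = self.frame[[inner, outer]].dropna()
        if sub.empty:
            return
        n_outer = sub.groupby(inner, observed=True)[outer].nunique()
        offenders = n_outer[n_outer > 1]
        if len(offenders):
            raise ValidationError(
                f"{inner} level(s) {list(offenders.index)} appear in multiple "
                f"{outer} levels: nesting violated"
            )

    def _check_replicate_groups(self) -> None:
        sub = self.frame.dropna(subset=["replicate_group"])
        if sub.empty:
            return
        for grp, rows in sub.groupby("replicate_group", observed=True):
            if rows["patient_id"].nunique() > 1:
                raise ValidationError(f"replicate_group {grp!r} spans several patients")
            if rows["sample_type"].nunique() > 1:
                raise ValidationError(f"replicate_group {grp!r} mixes sample types")
            if rows["extraction_batch"].nunique() < 2:
                raise ValidationError(
                    f"replicate_group {grp!r} does not span >=2 extraction batches"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def factor(self, name: str) -> pd.Series:
        if name not in self.frame.columns:
            raise KeyError(f"unknown design factor {name!r}")
        return self.frame[name]

    def samples_of_type(self, *sample_types: str) -> list[str]:
        mask = self.frame["sample_type"].isin(sample_types)
        return list(self.frame.index[mask])

    def subset(self, sample_ids) -> "StudyDesign":
        sub = self.frame.loc[list(sample_ids)].copy()
        # Singleton replicate groups after subsetting carry no pairing
        # information and would fail the >=2 batch invariant.
        counts = sub["replicate_group"].value_counts()
        lonely = counts[counts < 2].index
        sub.loc[sub["replicate_group"].isin(lonely), "replicate_group"] = pd.NA
        return StudyDesign(sub.reset_index())

    def align_with(self, table: AsvCountTable) -> None:
        missing = set(table.sample_ids) - set(self.frame.index)
        if missing:
            raise ValidationError(f"samples missing from design: {sorted(missing)}")


@dataclass
class TaxonomyTable:
    """Per-ASV lineage over the ranks domain..genus, plus a confidence.

    Empty ranks may only trail non-empty ones (a lineage is a prefix of
    the full rank path).
    """

    frame: pd.DataFrame
    ranks: tuple = field(default=RANKS)

    def __post_init__(self) -> None:
        df = self.frame
        if "asv_id" in df.columns:
            df = df.set_index("asv_id")
        if df.index.has_duplicates:
            raise ValidationError("duplicate ASV ids in taxonomy")
        for rank in self.ranks:
            if rank not in df.columns:
                df[rank] = ""
        df[list(self.ranks)] = df[list(self.ranks)].fillna("").astype(str)
        if "confidence" not in df.columns:
            df["confidence"] = np.nan
        lineages = df[list(self.ranks)].to_numpy()
        nonempty = lineages != ""
        # trailing-empty check: no non-empty rank after an empty one
        for i, row in enumerate(nonempty):
            seen_empty = False
            for flag in row:
                if not flag:
                    seen_empty = True
                elif seen_empty:
                    raise ValidationError(
                        f"lineage of {df.index[i]!r} has a gap (empty internal rank)"
                    )
        self.frame = df

    def lineage(self, asv_id: str) -> tuple:
        row = self.frame.loc[asv_id, list(self.ranks)]
        return tuple(v for v in row if v != "")

    def rank_value(self, asv_id: str, rank: str) -> str:
        return str(self.frame.loc[asv_id, rank])

    def subset(self, asv_ids) -> "TaxonomyTable":
        return TaxonomyTable(self.frame.loc[list(asv_ids)].reset_index(), self.ranks)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_count_table(path, fmt: str = "tsv") -> AsvCountTable:
    """Read an ASV count table from TSV or BIOM v1 (JSON) format.

    TSV dialect: first column holds ASV ids, header row holds sample ids.
    """
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.shape[0] == 0:
            raise ValidationError("no ASVs")
        return AsvCountTable(df)
    if fmt == "biom":
        with open(path) as fh:
            doc = json.load(fh)
        return _biom_v1_to_table(doc)
    raise ValueError(f"unknown count-table format {fmt!r}")


def write_count_table(table: AsvCountTable, path, fmt: str = "tsv") -> None:
    if fmt == "tsv":
        table.counts.rename_axis("asv_id").to_csv(path, sep="\t")
    elif fmt == "biom":
        with open(path, "w") as fh:
            json.dump(_table_to_biom_v1(table), fh)
    else:
        raise ValueError(f"unknown count-table format {fmt!r}")


def _table_to_biom_v1(table: AsvCountTable) -> dict:
    m = table.matrix
    rows_idx, cols_idx = np.nonzero(m)
    data = [[int(i), int(j), int(m[i, j])] for i, j in zip(rows_idx, cols_idx)]
    return {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "cfmdna",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": list(m.shape),
        "rows": [{"id": a, "metadata": None} for a in table.asv_ids],
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": data,
    }


def _biom_v1_to_table(doc: dict) -> AsvCountTable:
    shape = tuple(doc["shape"])
    asv_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    m = np.zeros(shape, dtype=np.int64)
    if doc.get("matrix_type") == "dense":
        m[:] = np.asarray(doc["data"])
    else:
        for i, j, v in doc["data"]:
            m[i, j] = v
    return AsvCountTable(pd.DataFrame(m, index=asv_ids, columns=sample_ids))


def read_design(path) -> StudyDesign:
    """Read a sample metadata TSV (sample_id, sample_type, factor columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample_id", "sample_type"} - set(df.columns)
    if missing:
        raise ValidationError(f"design TSV lacks columns: {sorted(missing)}")
    return StudyDesign(df)


def write_design(design: StudyDesign, path) -> None:
    design.frame.rename_axis("sample_id").to_csv(path, sep="\t")


def read_taxonomy(path) -> TaxonomyTable:
    """Read a QIIME-style taxonomy TSV.

    Columns: ``Feature ID``, ``Taxon`` (semicolon-delimited ranks, with or
    without ``g__``-style prefixes) and optional ``Confidence``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower().replace(" ", "_"): c for c in df.columns}
    fid = cols.get("feature_id", cols.get("asv_id"))
    taxon = cols.get("taxon", cols.get("lineage"))
    if fid is None or taxon is None:
        raise ValidationError("taxonomy TSV needs 'Feature ID' and 'Taxon' columns")
    records = []
    for _, row in df.iterrows():
        parts = [p.strip() for p in str(row[taxon]).split(";")]
        parts = [p.split("__", 1)[1] if "__" in p else p for p in parts]
        parts = (parts + [""] * len(RANKS))[: len(RANKS)]
        rec = {"asv_id": row[fid], **dict(zip(RANKS, parts))}
        if "confidence" in cols:
            rec["confidence"] = float(row[cols["confidence"]])
        records.append(rec)
    return TaxonomyTable(pd.DataFrame(records))


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    out = pd.DataFrame(
        {
            "Feature ID": tax.frame.index,
            "Taxon": [";".join(tax.lineage(a)) for a in tax.frame.index],
            "Confidence": tax.frame["confidence"].to_numpy(),
        }
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Preprocessing filters
# ---------------------------------------------------------------------------

NONTARGET_TOKENS = ("eukaryota", "mitochondria", "chloroplast")


def filter_nontarget_taxa(table: AsvCountTable, tax: TaxonomyTable) -> AsvCountTable:
    """Drop ASVs classified as eukaryota, mitochondria or chloroplast.

    Matching is case-insensitive against every rank of the lineage.
    """
    missing = set(table.asv_ids) - set(tax.frame.index)
    if missing:
        raise ValidationError(f"taxonomy missing for ASVs: {sorted(missing)[:5]}")
    keep = []
    for asv in table.asv_ids:
        lineage = " ".join(tax.lineage(asv)).lower()
        if not any(tok in lineage for tok in NONTARGET_TOKENS):
            keep.append(asv)
    if not keep:
        warnings.warn("all ASVs matched non-target lineages; empty table")
    return table.subset_asvs(keep)


def merge_technical_replicates(
    table: AsvCountTable, design: StudyDesign, key: str = "replicate_of"
) -> tuple[AsvCountTable, StudyDesign]:
    """Sum counts of technical (PCR) replicates of one biological sample.

    ``key`` is a design column whose value groups the samples to merge;
    samples with a missing key stay as singleton groups.  The merged sample
    takes the id of the group (or the sample's own id for singletons) and
    inherits the factors of the group's first member, which must agree on
    sample_type.
    """
    design.align_with(table)
    frame = design.frame.loc[table.sample_ids]
    group_key = frame[key] if key in frame.columns else pd.Series(pd.NA, frame.index)
    group_key = group_key.where(group_key.notna(), frame.index.to_series())

    merged_cols = {}
    merged_rows = []
    for grp, members in group_key.groupby(group_key, observed=True):
        ids = list(members.index)
        types = frame.loc[ids, "sample_type"].unique()
        if len(types) > 1:
            raise ValidationError(f"replicate group {grp!r} mixes sample types {types}")
        merged_cols[str(grp)] = table.counts[ids].sum(axis=1)
        row = frame.loc[ids[0]].copy()
        row.name = str(grp)
        merged_rows.append(row)
    out_counts = pd.DataFrame(merged_cols)
    out_frame = pd.DataFrame(merged_rows)
    out_frame.index.name = "sample_id"
    if key in out_frame.columns:
        out_frame = out_frame.drop(columns=[key])
    return AsvCountTable(out_counts), StudyDesign(out_frame.reset_index())


def filter_low_abundance(
    table: AsvCountTable, design: StudyDesign, floor_pct: float = 0.01
) -> AsvCountTable:
    """Zero out ASVs below an abundance floor within each sample-type stratum.

    Within each sample type, an ASV whose share of that stratum's total
    reads is strictly below ``floor_pct`` percent is removed from that
    stratum (its counts there are set to zero).  An ASV kept in one stratum
    may be removed from another.  ASVs left with zero counts everywhere are
    dropped from the table.
    """
    design.align_with(table)
    counts = table.counts.copy()
    types = design.frame.loc[table.sample_ids, "sample_type"]
    for stype in types.unique():
        cols = list(types.index[types == stype])
        stratum_total = counts[cols].to_numpy().sum()
        if stratum_total == 0:
            raise ValidationError(f"sample type {stype!r} stratum has zero reads")
        share_pct = 100.0 * counts[cols].sum(axis=1) / stratum_total
        below = share_pct < floor_pct
        counts.loc[below, cols] = 0
    return AsvCountTable(counts).drop_empty_asvs()


def rarefy(table: AsvCountTable, depth: int, seed: int) -> AsvCountTable:
    """Subsample each sample to ``depth`` reads without replacement.

    Each sample is an independent multivariate-hypergeometric draw seeded
    from ``(seed, sample index)``, so per-sample output does not depend on
    which other samples are present.  Samples with fewer than ``depth``
    reads are dropped with a warning.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    out = {}
    for idx, sample in enumerate(table.sample_ids):
        col = table.counts[sample].to_numpy()
        total = int(col.sum())
        if total < depth:
            logger.warning("dropping sample %s: %d reads < depth %d", sample, total, depth)
            continue
        if total == depth:
            out[sample] = col
            continue
        rng = np.random.default_rng([seed, idx])
        out[sample] = rng.multivariate_hypergeometric(col, depth)
    if not out:
        raise ValidationError("no samples reach the rarefaction depth")
    return AsvCountTable(pd.DataFrame(out, index=table.asv_ids))


def transform(
    table: AsvCountTable,
    kind: str,
    offset: float = 1.0,
    prior_cpm: float = 0.5,
) -> pd.DataFrame:
    """Transform counts to a real-valued matrix.

    kind:
      - ``relative``: per-sample fractions.
      - ``sqrt``: element-wise square root of relative abundances.
      - ``clr``: centred log ratio of counts + ``offset`` (natural log).
      - ``log_cpm``: log2 counts per million with prior count ``prior_cpm``.
    """
    x = table.counts.to_numpy(dtype=float)
    libsize = x.sum(axis=0)
    if kind in ("relative", "sqrt"):
        if np.any(libsize == 0):
            raise ValidationError("zero library size")
        rel = x / libsize
        return pd.DataFrame(
            np.sqrt(rel) if kind == "sqrt" else rel,
            index=table.asv_ids,
            columns=table.sample_ids,
        )
    if kind == "clr":
        if offset <= 0:
            raise ValueError("clr offset must be positive")
        logx = np.log(x + offset)
        clr = logx - logx.mean(axis=0)
        return pd.DataFrame(clr, index=table.asv_ids, columns=table.sample_ids)
    if kind == "log_cpm":
        if np.any(libsize == 0):
            raise ValidationError("zero library size")
        cpm = 1e6 * (x + prior_cpm) / (libsize + 2 * prior_cpm)
        return pd.DataFrame(np.log2(cpm), index=table.asv_ids, columns=table.sample_ids)
    raise ValueError(f"unknown transform {kind!r}")
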