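"""End-to-end decontamination pipeline: count table -> high-confidence ASVs.

Stages: preprocessing (non-target taxa, replicate merging, abundance
floor), then the four filtering criteria evaluated independently —
(i) no batch effect across technical variables, (ii) higher prevalence
in plasma than DENCs, (iii) replicate-detection agreement where a
replicate batch pair exists, (iv) taxonomy-evidence retention — and
finally their intersection.  Evaluating criteria independently (rather
than short-circuiting) lets the tally report each criterion separately
and in combination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import batch_da, kappa, prevalence, taxon_filter
from .tables import AsvCountTable, StudyDesign, TaxonomyTable, filter_low_abundance, filter_nontarget_taxa, merge_technical_replicates

logger = logging.getLogger(__name__)

ABUNDANCE_CLASSES = ("low", "medium", "high")  # <0.1%, 0.1-1%, >1% mean rel. abundance


@dataclass
class PipelineConfig:
    floor_pct: float = 0.01
    fdr_cut: float = 0.05
    prevalence_threshold: float = prevalence.DEFAULT_THRESHOLD
    kappa_min: float = 0.4
    kappa_alpha: float = 0.05
    include_dencs_in_criterion_i: bool = False
    merge_key: str | None = None          # design column grouping PCR replicates
    apply_criterion_iv: bool = True
    #: which ASVs criterion (iii) gates: "exclusive" = only ASVs whose plasma
    #: detections all lie in the replicate batch pair; "observed" = every ASV
    #: detected in the pair, regardless of presence elsewhere
    criterion_iii_scope: str = "exclusive"


@dataclass
class DecontamReport:
    """Per-ASV record of every criterion plus the final verdict."""

    frame: pd.DataFrame
    fits: dict = field(default_factory=dict)
    prevalence_scores: object = None
    kappa_result: object = None
    config: PipelineConfig = field(default_factory=PipelineConfig)

    def final_list(self) -> list:
        return list(self.frame.index[self.frame["final_high_confidence"]])

    def to_tsv(self, path) -> None:
        self.frame.rename_axis("asv_id").to_csv(path, sep="\t")


def abundance_class(mean_relabund_pct: float) -> str:
    """Class by mean relative abundance across plasma samples, in percent:
    low < 0.1, medium 0.1-1, high > 1."""
    if mean_relabund_pct > 1.0:
        return "high"
    if mean_relabund_pct >= 0.1:
        return "medium"
    return "low"


def find_replicate_pair(design: StudyDesign) -> tuple[str, str] | None:
    """The pair of extraction batches linked by replicate groups, if any."""
    sub = design.frame.dropna(subset=["replicate_group"])
    if sub.empty:
        return None
    batches = sorted(sub["extraction_batch"].astype(str).unique())
    if len(batches) != 2:
        logger.warning("replicate groups span %d batches; expected 2", len(batches))
        return None
    return batches[0], batches[1]


def identify_high_confidence_asvs(
    table: AsvCountTable,
    design: StudyDesign,
    taxonomy: TaxonomyTable | None = None,
    lists: taxon_filter.EvidenceLists | None = None,
    config: PipelineConfig | None = None,
) -> DecontamReport:
    """Run the full decontamination framework on one cohort."""
    config = config or PipelineConfig()
    design.align_with(table)

    # --- preprocessing
    if taxonomy is not None:
        table = filter_nontarget_taxa(table, taxonomy)
    if config.merge_key:
        table, design = merge_technical_replicates(table, design, config.merge_key)
    table = filter_low_abundance(table, design, config.floor_pct)

    plasma = design.samples_of_type("plasma")
    dencs = design.samples_of_type("plasma_denc")
    if not plasma:
        raise ValueError("no plasma samples in the design")
    if not dencs:
        raise ValueError(
            "criterion (ii) needs plasma DENC samples; none found in the design"
        )

    # candidate set: ASVs observed in any plasma sample
    plasma_counts = table.counts[plasma]
    candidates = list(plasma_counts.index[plasma_counts.sum(axis=1) > 0])
    cand_table = table.subset_asvs(candidates)

    rel = plasma_counts.div(plasma_counts.sum(axis=0), axis=1)
    mean_rel_pct = (100.0 * rel.mean(axis=1)).loc[candidates]

    # --- criterion (i)
    flags, fits = batch_da.technical_variable_screen(
        table,
        design,
        fdr_cut=config.fdr_cut,
        include_dencs=config.include_dencs_in_criterion_i,
    )
    pass_i = ~flags.loc[candidates]

    # --- criterion (ii)
    sub_ids = plasma + dencs
    scores = prevalence.prevalence_score_batched(
        cand_table.subset_samples(sub_ids),
        design,
        threshold=config.prevalence_threshold,
    )
    pass_ii = scores.passes().loc[candidates]

    # --- criterion (iii)
    pair = find_replicate_pair(design)
    if pair is None:
        logger.info("no replicate batch pair: criterion (iii) skipped")
        kr = None
        applicable = pd.Series(False, index=candidates)
        pass_iii = pd.Series(True, index=candidates)
    else:
        kr = kappa.replicate_agreement_filter(
            cand_table, design, pair,
            kappa_min=config.kappa_min, alpha=config.kappa_alpha,
        )
        applicable = kr.table["applicable"].loc[candidates]
        if config.criterion_iii_scope == "exclusive":
            # gate only ASVs whose plasma detections are confined to the
            # replicate pair; ASVs also seen in other batches are judged
            # on criteria (i), (ii) and (iv) alone
            pair_batches = {str(pair[0]), str(pair[1])}
            outside = [
                s for s in plasma
                if str(design.frame.loc[s, "extraction_batch"]) not in pair_batches
            ]
            seen_outside = plasma_counts[outside].sum(axis=1).loc[candidates] > 0
            applicable = applicable & ~seen_outside
        elif config.criterion_iii_scope != "observed":
            raise ValueError(f"unknown criterion_iii_scope {config.criterion_iii_scope!r}")
        # where not applicable the criterion imposes no constraint
        pass_iii = kr.table["pass"].loc[candidates].where(applicable, True).astype(bool)

    # --- criterion (iv)
    if config.apply_criterion_iv and taxonomy is not None and lists is not None:
        categories = taxon_filter.categorise_asvs(taxonomy, candidates, lists)
        retained_iv = pd.Series(
            [c not in taxon_filter.DISCARD for c in categories], index=candidates
        )
    else:
        categories = pd.Series("unclassified", index=candidates)
        retained_iv = pd.Series(True, index=candidates)

    final = pass_i & pass_ii & pass_iii & retained_iv
    frame = pd.DataFrame(
        {
            "mean_relabund_pct": mean_rel_pct,
            "abundance_class": mean_rel_pct.map(abundance_class),
            "criterion_i_pass": pass_i,
            "criterion_ii_pass": pass_ii,
            "criterion_iii_applicable": applicable,
            "criterion_iii_pass": pass_iii,
            "criterion_iv_category": categories,
            "criterion_iv_retained": retained_iv,
            "final_high_confidence": final,
        },
        index=candidates,
    )
    return DecontamReport(frame, fits, scores, kr, config)


def tally_report(report: DecontamReport) -> pd.DataFrame:
    """Tally of ASV counts (and column percentages) per criterion and
    abundance class, mirroring the criterion-by-criterion summary table."""
    frame = report.frame
    classes = {c: frame.index[frame["abundance_class"] == c] for c in ABUNDANCE_CLASSES}

    def row(name: str, members) -> dict:
        members = set(members)
        rec = {"row": name}
        for col, idx in (("all", frame.index), *classes.items()):
            total = len(idx)
            n = len(members & set(idx))
            rec[col] = n
            rec[f"{col}_pct"] = round(100.0 * n / total, 2) if total else 0.0
        return rec

    rows = [row("total", frame.index)]
    # criterion (i) per technical variable
    for var, fit in report.fits.items():
        hit = set(fit.table.loc[fit.table["fdr"] <= report.config.fdr_cut, "asv_id"])
        rows.append(row(f"criterion_i_no_effect_{var}", set(frame.index) - hit))
    rows.append(row("criterion_i_combined", frame.index[frame["criterion_i_pass"]]))
    # criterion (ii) per batch and combined
    if report.prevalence_scores is not None:
        st = report.prevalence_scores.table
        thr = report.prevalence_scores.threshold
        for b in [c for c in st.columns if c not in ("combined", "classification")]:
            ok = st.index[(st[b] >= thr) | st[b].isna()]
            ok = [a for a in ok if a in frame.index and not np.isnan(st.loc[a, b])]
            rows.append(row(f"criterion_ii_batch_{b}", ok))
    rows.append(row("criterion_ii_combined", frame.index[frame["criterion_ii_pass"]]))
    rows.append(
        row(
            "criterion_iii",
            frame.index[frame["criterion_iii_applicable"] & frame["criterion_iii_pass"]],
        )
    )
    combined = frame["criterion_i_pass"] & frame["criterion_ii_pass"] & frame["criterion_iii_pass"]
    rows.append(row("combined_strategy", frame.index[combined]))
    rows.append(row("final_list", frame.index[frame["final_high_confidence"]]))
    return pd.DataFrame(rows).set_index("row")
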