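"""Criterion (ii): prevalence-based contaminant scoring against DENCs.

Reagent contaminants are at least as prevalent in DNA-extraction negative
controls (DENCs) as in true samples, because controls carry nothing but
reagent DNA.  Each ASV's presence/absence 2x2 table (plasma vs DENC) is
scored per extraction batch: the score is a one-sided tail probability
oriented so that *small* values indicate the contaminant direction
(higher prevalence fraction in controls).  Per-batch scores are combined
by their minimum and thresholded (default 0.55, strict less-than) to
classify each ASV as contaminant or real.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import AsvCountTable, StudyDesign

DEFAULT_THRESHOLD = 0.55


def presence_matrix(table: AsvCountTable, min_count: int = 1) -> pd.DataFrame:
    """Boolean ASV x sample detection matrix (count >= min_count)."""
    return table.counts >= min_count


def prevalence_score_single(
    present_samples: int,
    absent_samples: int,
    present_controls: int,
    absent_controls: int,
) -> float:
    """One-sided prevalence score for a single 2x2 presence table.

    Uses the chi-square (1 df, no continuity correction) two-sided tail
    probability t, folded to one side: score = t/2 when the control
    prevalence fraction exceeds the sample fraction (contaminant
    direction), else 1 - t/2.  When any expected cell is < 5 or the total
    is < 20, a one-sided hypergeometric (Fisher) tail on the number of
    control presences replaces it, as the mid-P value
    P(X > c) + P(X = c)/2 so that uninformative tables (e.g. an ASV
    present in every sample and every control) score 0.5 rather than 1,
    matching the chi-square branch's orientation convention.
    """
    a, b = int(present_samples), int(absent_samples)
    c, d = int(present_controls), int(absent_controls)
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell counts")
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty 2x2 table")
    n_samp, n_ctrl = a + b, c + d
    n_pres = a + c
    if n_pres == 0:
        raise ValueError("ASV present nowhere: score undefined")
    if n_samp == 0 or n_ctrl == 0:
        raise ValueError("need at least one sample and one control")

    expected = np.outer([n_samp, n_ctrl], [n_pres, n - n_pres]) / n
    use_fisher = (expected < 5).any() or n < 20
    if use_fisher:
        # mid-P hypergeometric tail on control presences, small when the
        # controls hold unexpectedly many of the presences
        rv = stats.hypergeom(n, n_pres, n_ctrl)
        return float(rv.sf(c) + 0.5 * rv.pmf(c))
    obs = np.array([[a, b], [c, d]], dtype=float)
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    t = float(stats.chi2.sf(chi2, df=1))
    frac_ctrl = c / n_ctrl
    frac_samp = a / n_samp
    if frac_ctrl > frac_samp:
        return t / 2.0
    return 1.0 - t / 2.0


@dataclass
class PrevalenceScore:
    """Per-ASV per-batch scores, their minimum, and the classification."""

    table: pd.DataFrame  # index asv_id; per-batch columns, 'combined', 'classification'
    threshold: float

    def passes(self) -> pd.Series:
        """Criterion (ii) passers: ASVs classified real."""
        return self.table["classification"] == "real"

    def to_tsv(self, path) -> None:
        self.table.rename_axis("asv_id").to_csv(path, sep="\t")


def prevalence_score_batched(
    table: AsvCountTable,
    design: StudyDesign,
    batch_var: str = "extraction_batch",
    threshold: float = DEFAULT_THRESHOLD,
    sample_type: str = "plasma",
    control_type: str = "plasma_denc",
    min_count: int = 1,
) -> PrevalenceScore:
    """Score every ASV per extraction batch and combine by minimum.

    Batches where an ASV occurs in neither samples nor controls contribute
    no score; batches lacking any negative control are skipped with a
    warning.  Classification is ``contaminant`` iff the combined (minimum)
    score is strictly below the threshold.
    """
    design.align_with(table)
    pres = presence_matrix(table, min_count=min_count)
    frame = design.frame.loc[table.sample_ids]
    batches = sorted(frame[batch_var].dropna().astype(str).unique())

    per_batch: dict[str, pd.Series] = {}
    for batch in batches:
        in_batch = frame[batch_var].astype(str) == batch
        samp = list(frame.index[in_batch & (frame["sample_type"] == sample_type)])
        ctrl = list(frame.index[in_batch & (frame["sample_type"] == control_type)])
        if not ctrl:
            warnings.warn(f"batch {batch!r} has no negative controls; skipped")
            continue
        if not samp:
            warnings.warn(f"batch {batch!r} has no {sample_type} samples; skipped")
            continue
        a = pres[samp].sum(axis=1)
        c = pres[ctrl].sum(axis=1)
        scores = pd.Series(np.nan, index=table.asv_ids)
        occurs = (a + c) > 0
        for asv in table.counts.index[occurs]:
            scores[asv] = prevalence_score_single(
                int(a[asv]), len(samp) - int(a[asv]), int(c[asv]), len(ctrl) - int(c[asv])
            )
        per_batch[batch] = scores

    if not per_batch:
        raise ValueError("no batch with both samples and negative controls")
    out = pd.DataFrame(per_batch)
    combined = out.min(axis=1, skipna=True)
    if combined.isna().any():
        # occurs only in batches that could not be scored (no controls):
        # no prevalence evidence either way, so the ASV cannot be called real
        warnings.warn(
            f"{int(combined.isna().sum())} ASV(s) occur only in unscored "
            "batches; left unscored (not classified real)"
        )
    out["combined"] = combined
    out["classification"] = np.select(
        [combined.isna(), combined < threshold], ["unscored", "contaminant"], "real"
    )
    return PrevalenceScore(out, threshold)
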