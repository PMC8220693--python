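"""Criterion (iii): replicate-detection agreement via Cohen's kappa.

A genuine plasma ASV should be detected in the *same patients* when their
samples are re-extracted in a second DNA-extraction batch, whereas a
stochastic contaminant hits samples at random.  For each ASV, detection
across matched replicate pairs forms a 2x2 agreement table; Cohen's kappa
with the large-sample null standard error (Fleiss) provides a
significance test.  An ASV passes when kappa > 0.4 and p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import AsvCountTable, StudyDesign


def cohen_kappa(a: int, b: int, c: int, d: int) -> tuple[float, float, float]:
    """Cohen's kappa, null z statistic and two-sided p for a 2x2 table.

    Cells: a = detected/detected, b = detected/absent, c = absent/detected,
    d = absent/absent over matched pairs.  The z statistic uses the
    large-sample standard error of kappa under the null of independent
    ratings (Fleiss, Cohen & Everitt).
    """
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n < 1:
        raise ValueError("empty agreement table")
    po = (a + d) / n
    p_row = np.array([(a + b) / n, (c + d) / n])
    p_col = np.array([(a + c) / n, (b + d) / n])
    pe = float(p_row @ p_col)
    if pe >= 1.0 - 1e-15:
        raise ValueError("degenerate marginals: kappa undefined (pe == 1)")
    kappa = (po - pe) / (1.0 - pe)
    # Fleiss null variance of kappa
    num = pe + pe**2 - float(np.sum(p_row * p_col * (p_row + p_col)))
    se0 = np.sqrt(max(num, 0.0)) / ((1.0 - pe) * np.sqrt(n))
    if se0 == 0:
        # marginals leave no room for chance agreement variation; kappa is
        # defined but carries no significance test
        return float(kappa), float("nan"), float("nan")
    z = kappa / se0
    p = 2.0 * stats.norm.sf(abs(z))
    return float(kappa), float(z), float(p)


@dataclass
class KappaResult:
    """Per-ASV agreement tables and the pass/fail verdict of criterion (iii)."""

    table: pd.DataFrame  # index asv_id; cols a,b,c,d,kappa,z,p,applicable,pass
    batch_pair: tuple[str, str]
    kappa_min: float
    alpha: float

    def to_tsv(self, path) -> None:
        self.table.rename_axis("asv_id").to_csv(path, sep="\t")


def matched_replicate_pairs(
    design: StudyDesign, batch_pair: tuple[str, str], sample_type: str = "plasma"
) -> list[tuple[str, str]]:
    """Sample-id pairs (batch1 sample, batch2 sample) linked by
    replicate_group."""
    b1, b2 = str(batch_pair[0]), str(batch_pair[1])
    frame = design.frame
    sub = frame[(frame["sample_type"] == sample_type) & frame["replicate_group"].notna()]
    pairs = []
    for _, rows in sub.groupby("replicate_group", observed=True):
        batches = rows["extraction_batch"].astype(str)
        s1 = list(rows.index[batches == b1])
        s2 = list(rows.index[batches == b2])
        if len(s1) == 1 and len(s2) == 1:
            pairs.append((s1[0], s2[0]))
    return pairs


def replicate_agreement_filter(
    table: AsvCountTable,
    design: StudyDesign,
    pair: tuple[str, str],
    kappa_min: float = 0.4,
    alpha: float = 0.05,
    min_count: int = 1,
) -> KappaResult:
    """Evaluate criterion (iii) for every ASV across a replicate batch pair.

    applicable = the ASV is detected in at least one sample of the paired
    batches and its agreement table is non-degenerate; pass = applicable
    and kappa > kappa_min and p < alpha (strict comparisons).
    """
    sample_pairs = matched_replicate_pairs(design, pair)
    if not sample_pairs:
        raise ValueError(f"no matched replicate pairs between batches {pair}")
    det = table.counts >= min_count
    left = det[[p[0] for p in sample_pairs]].to_numpy()
    right = det[[p[1] for p in sample_pairs]].to_numpy()
    a = (left & right).sum(axis=1)
    b = (left & ~right).sum(axis=1)
    c = (~left & right).sum(axis=1)
    d = (~left & ~right).sum(axis=1)

    rows = []
    for i, asv in enumerate(table.asv_ids):
        rec = {"a": a[i], "b": b[i], "c": c[i], "d": d[i], "kappa": np.nan,
               "z": np.nan, "p": np.nan, "applicable": False, "pass": False}
        if a[i] + b[i] + c[i] > 0:  # detected somewhere in the paired batches
            try:
                k, z, p = cohen_kappa(a[i], b[i], c[i], d[i])
            except ValueError:
                pass  # degenerate marginals: not applicable
            else:
                rec.update(kappa=k, z=z, p=p, applicable=True,
                           **{"pass": bool(k > kappa_min and p < alpha)})
        rows.append(rec)
    out = pd.DataFrame(rows, index=table.asv_ids)
    return KappaResult(out, (str(pair[0]), str(pair[1])), kappa_min, alpha)
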