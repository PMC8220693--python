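"""PERMANOVA with sequential sums of squares and blocked permutations.

The statistic follows the classical partitioning of a Gower-centred
inner-product matrix derived from squared dissimilarities: for an ordered
sequence of model terms, each term's sum of squares is the increment in
explained trace when the term's columns join the hat matrix (Type I,
matching the ``adonis`` convention).  Significance comes from permuting
sample labels, either freely or — for repeated-measures designs —
restricted so every permutation maps each sample to a sample of the same
block (subject), which preserves the within-subject correlation structure
under the null.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import qr
from skbio import DistanceMatrix

from .tables import StudyDesign

logger = logging.getLogger(__name__)


@dataclass
class PermanovaResult:
    """Per-term ANOVA-style table plus the permutation protocol used."""

    table: pd.DataFrame  # rows: terms, Residual, Total; cols: df, SumOfSqs, F, R2, p
    n_permutations: int
    seed: int | None

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "p"])

    def to_tsv(self, path) -> None:
        self.table.rename_axis("term").to_csv(path, sep="\t")


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = a.shape[0]
    c = np.eye(n) - np.ones((n, n)) / n
    return c @ a @ c


def _dummies(values: pd.Series) -> np.ndarray:
    """Treatment-coded dummy columns (first level dropped)."""
    cats = pd.Categorical(values.astype(str))
    if len(cats.categories) < 2:
        raise ValueError(f"factor {values.name!r} has a single level (zero df)")
    m = pd.get_dummies(cats, drop_first=True).to_numpy(dtype=float)
    return m


def _term_columns(design: StudyDesign, term: str, ids: list) -> np.ndarray:
    frame = design.frame.loc[ids]
    parts = term.split(":")
    mats = [_dummies(frame[p]) for p in parts]
    out = mats[0]
    for m in mats[1:]:
        out = np.einsum("ni,nj->nij", out, m).reshape(len(ids), -1)
    return out


def _hat(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Projection matrix onto the column space of x, and its rank."""
    q, r, _ = qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int(np.sum(diag > diag.max() * max(x.shape) * np.finfo(float).eps))
    q = q[:, :rank]
    return q @ q.T, rank


def _block_permutation(rng: np.random.Generator, block_indices: list[np.ndarray], n: int) -> np.ndarray:
    perm = np.arange(n)
    for idx in block_indices:
        perm[idx] = rng.permutation(idx)
    return perm


def permanova(
    dist: DistanceMatrix,
    design: StudyDesign,
    terms: list[str],
    n_perm: int = 999,
    seed: int | None = 0,
    blocks: str | None = None,
    permutations=None,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Parameters
    ----------
    terms
        Ordered model terms; interactions as ``"a:b"``.  Sums of squares
        are sequential, so order matters.
    blocks
        Optional design factor naming the subject/block; when given,
        permutations shuffle labels only within each block
        (repeated-measures-aware mode).
    permutations
        Explicit iterable of index permutations overriding the random
        protocol (used for exact enumeration on small designs).
    """
    ids = list(dist.ids)
    missing = set(ids) - set(design.frame.index)
    if missing:
        raise ValueError(f"samples missing from design: {sorted(missing)}")
    n = len(ids)
    g = _gower_center(dist.data)
    ss_total = float(np.trace(g))

    # sequential projection increments
    x = np.ones((n, 1))
    h_prev, rank_prev = _hat(x)
    increments, dfs = [], []
    for term in terms:
        x = np.hstack([x, _term_columns(design, term, ids)])
        h, rank = _hat(x)
        df = rank - rank_prev
        if df == 0:
            raise ValueError(f"term {term!r} adds no degrees of freedom (aliased)")
        increments.append(h - h_prev)
        dfs.append(df)
        h_prev, rank_prev = h, rank
    resid_proj = np.eye(n) - h_prev
    df_resid = n - rank_prev
    if df_resid <= 0:
        raise ValueError("fewer samples than model degrees of freedom + 1")

    def _ss(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        ss_terms = np.array([float(np.sum(inc * gmat)) for inc in increments])
        ss_res = float(np.sum(resid_proj * gmat))
        return ss_terms, ss_res

    ss_terms, ss_resid = _ss(g)
    f_obs = (ss_terms / np.array(dfs)) / (ss_resid / df_resid)

    # permutation protocol
    if permutations is not None:
        perm_list = [np.asarray(p) for p in permutations]
        n_used = len(perm_list)
        exceed = np.zeros(len(terms))
        for p in perm_list:
            gp = g[np.ix_(p, p)]
            ss_t, ss_r = _ss(gp)
            f_p = (ss_t / np.array(dfs)) / (ss_r / df_resid)
            exceed += f_p >= f_obs - 1e-12
        p_vals = exceed / n_used
        n_perm_eff = n_used
    else:
        rng = np.random.default_rng(seed)
        if blocks is not None:
            blk = design.frame.loc[ids, blocks].to_numpy()
            block_indices = [np.flatnonzero(blk == b) for b in pd.unique(blk)]
            singletons = sum(1 for idx in block_indices if len(idx) == 1)
            if singletons:
                logger.info("%d singleton blocks contribute no permutation freedom", singletons)
            draw = lambda: _block_permutation(rng, block_indices, n)  # noqa: E731
        else:
            draw = lambda: rng.permutation(n)  # noqa: E731
        exceed = np.ones(len(terms))  # identity permutation in the null set
        for _ in range(n_perm):
            p = draw()
            gp = g[np.ix_(p, p)]
            ss_t, ss_r = _ss(gp)
            f_p = (ss_t / np.array(dfs)) / (ss_r / df_resid)
            exceed += f_p >= f_obs - 1e-12
        p_vals = exceed / (n_perm + 1)
        n_perm_eff = n_perm

    rows = []
    for term, df, ss, f, p in zip(terms, dfs, ss_terms, f_obs, p_vals):
        rows.append((term, df, ss, f, ss / ss_total, p))
    rows.append(("Residual", df_resid, ss_resid, np.nan, ss_resid / ss_total, np.nan))
    rows.append(("Total", n - 1, ss_total, np.nan, 1.0, np.nan))
    out = pd.DataFrame(rows, columns=["term", "df", "SumOfSqs", "F", "R2", "p"]).set_index("term")
    return PermanovaResult(out, n_perm_eff, seed)


def rma_permanova(
    dist: DistanceMatrix,
    design: StudyDesign,
    terms: list[str],
    blocks: str,
    n_perm: int = 999,
    seed: int | None = 0,
) -> PermanovaResult:
    """Repeated-measures-aware PERMANOVA: permutations blocked within subject."""
    return permanova(dist, design, terms, n_perm=n_perm, seed=seed, blocks=blocks)


def pairwise_permanova(
    dist: DistanceMatrix,
    design: StudyDesign,
    factor: str,
    n_perm: int = 999,
    seed: int | None = 0,
    blocks: str | None = None,
) -> dict[tuple[str, str], PermanovaResult]:
    """One two-level PERMANOVA per unordered level pair of ``factor``."""
    ids = list(dist.ids)
    levels = sorted(pd.unique(design.frame.loc[ids, factor].astype(str)))
    if len(levels) < 2:
        raise ValueError("pairwise test needs a factor with >=2 levels")
    results = {}
    for a, b in itertools.combinations(levels, 2):
        keep = [
            s for s in ids if str(design.frame.loc[s, factor]) in (a, b)
        ]
        counts = design.frame.loc[keep, factor].astype(str).value_counts()
        if (counts < 2).any():
            raise ValueError(f"level with <2 samples in pair ({a}, {b})")
        sub = dist.filter(keep)
        results[(a, b)] = permanova(
            sub, design, [factor], n_perm=n_perm, seed=seed, blocks=blocks
        )
    return results


def exact_group_permutation_p(dist: DistanceMatrix, labels: list) -> float:
    """Brute-force enumeration p-value for a one-factor PERMANOVA.

    Enumerates every permutation of the label vector (so every
    relabelling is weighted equally) and returns the fraction with a
    pseudo-F at least as large as observed.  Only feasible for tiny n.
    """
    labels = np.asarray([str(v) for v in labels])
    n = len(labels)
    g = _gower_center(dist.data)

    def f_stat(lab: np.ndarray) -> float:
        x = np.ones((n, 1))
        x = np.hstack([x, pd.get_dummies(pd.Categorical(lab), drop_first=True).to_numpy(float)])
        h, rank = _hat(x)
        ss_model = float(np.sum((h - np.ones((n, n)) / n) * g))
        ss_res = float(np.sum((np.eye(n) - h) * g))
        return (ss_model / (rank - 1)) / (ss_res / (n - rank))

    f_obs = f_stat(labels)
    count = total = 0
    for p in itertools.permutations(range(n)):
        total += 1
        if f_stat(labels[list(p)]) >= f_obs - 1e-12:
            count += 1
    return count / total
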