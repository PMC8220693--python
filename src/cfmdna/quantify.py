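"""ddPCR absolute quantification and GEE group comparisons.

Droplet digital PCR partitions a reaction into ~20000 droplets; the
fraction of positive droplets is Poisson-corrected into a mean copy
number per droplet and hence an absolute concentration.  Concentrations
(and alpha-diversity values) are compared between plasma and negative
controls with generalised estimating equations, which give valid robust
inference when the same patient contributes samples to several
extraction batches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .kappa import cohen_kappa

#: nominal droplet partition volume of the ddPCR platform, in microlitres
DEFAULT_DROPLET_VOLUME_UL = 8.5e-4

MIN_DROPLETS = 10000


@dataclass
class DdpcrReaction:
    """One ddPCR well: droplet counts for a single replicate reaction."""

    droplets_total: int
    droplets_positive: int
    sample_id: str = ""
    replicate_index: int = 0
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_UL

    def __post_init__(self) -> None:
        if not 0 <= self.droplets_positive <= self.droplets_total:
            raise ValueError("need 0 <= positive droplets <= total droplets")
        if self.droplets_total < MIN_DROPLETS:
            warnings.warn(
                f"{self.droplets_total} droplets < {MIN_DROPLETS}: "
                "quantification below the recommended partition count"
            )


def poisson_concentration(rxn: DdpcrReaction) -> float:
    """Copies per microlitre of reaction from the positive-droplet fraction.

    lambda = -ln(1 - k/n) is the mean copy number per droplet; dividing by
    the droplet volume gives the concentration.  A saturated reaction
    (k == n) has no finite estimate.
    """
    k, n = rxn.droplets_positive, rxn.droplets_total
    if k == n:
        raise ValueError("saturated reaction (all droplets positive): lower bound only")
    lam = -np.log1p(-k / n)
    return float(lam / rxn.droplet_volume)


def copies_per_ml_source(conc_dna: float, elution_volume_ul: float, source_volume_ml: float) -> float:
    """Convert eluate concentration (copies/ul) to copies per ml of source
    fluid, e.g. 50 ul eluate from 2 ml plasma."""
    if elution_volume_ul <= 0 or source_volume_ml <= 0:
        raise ValueError("volumes must be positive")
    return conc_dna * elution_volume_ul / source_volume_ml


def reaction_copies(rxn: DdpcrReaction, reaction_volume_ul: float = 25.0) -> float:
    """Total amplifiable molecules in the analysed partitions."""
    k, n = rxn.droplets_positive, rxn.droplets_total
    if k == n:
        raise ValueError("saturated reaction")
    lam = -np.log1p(-k / n)
    return float(lam * n)


def detect_call(replicate_copies) -> bool:
    """Detection rule: >= 2 summed copies across the duplicate reactions."""
    copies = list(replicate_copies)
    if len(copies) < 2:
        raise ValueError("detection calls require at least duplicate reactions")
    return float(np.sum(copies)) >= 2.0


def read_ddpcr_wells(path) -> pd.DataFrame:
    """Read a ddPCR well table CSV: sample_id, replicate, droplets_total,
    droplets_positive and optional target column."""
    df = pd.read_csv(path)
    required = {"sample_id", "replicate", "droplets_total", "droplets_positive"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ddPCR CSV lacks columns: {sorted(missing)}")
    return df


def quantify_wells(
    wells: pd.DataFrame,
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_UL,
    elution_volume_ul: float = 50.0,
    source_volume_ml: float = 2.0,
) -> pd.DataFrame:
    """Per-sample concentrations, copies/ml of source, and detection calls."""
    out = []
    for sample, grp in wells.groupby("sample_id"):
        concs, copies = [], []
        for _, row in grp.iterrows():
            rxn = DdpcrReaction(
                int(row["droplets_total"]),
                int(row["droplets_positive"]),
                sample_id=str(sample),
                replicate_index=int(row["replicate"]),
                droplet_volume=droplet_volume,
            )
            concs.append(poisson_concentration(rxn))
            copies.append(reaction_copies(rxn))
        detected = detect_call(copies) if len(copies) >= 2 else np.nan
        mean_conc = float(np.mean(concs))
        out.append(
            {
                "sample_id": sample,
                "n_replicates": len(concs),
                "copies_per_ul": mean_conc,
                "copies_per_ml_source": copies_per_ml_source(
                    mean_conc, elution_volume_ul, source_volume_ml
                ),
                "total_copies": float(np.sum(copies)),
                "detected": detected,
            }
        )
    return pd.DataFrame(out).set_index("sample_id")


def agreement_with_sequencing(
    ddpcr_calls, seq_presence, ddpcr_conc, seq_abund
) -> tuple[float, float, float]:
    """Agreement of ddPCR and sequencing: Cohen's kappa on detection calls
    plus Spearman correlation of the quantitative values.

    Returns (kappa, kappa p-value, spearman rho).
    """
    x = np.asarray(ddpcr_calls, dtype=bool)
    y = np.asarray(seq_presence, dtype=bool)
    if len(x) != len(y):
        raise ValueError("misaligned call vectors")
    a = int(np.sum(x & y))
    b = int(np.sum(x & ~y))
    c = int(np.sum(~x & y))
    d = int(np.sum(~x & ~y))
    kappa, _z, p = cohen_kappa(a, b, c, d)
    conc = np.asarray(ddpcr_conc, float)
    abund = np.asarray(seq_abund, float)
    if len(conc) < 3:
        raise ValueError("Spearman correlation needs >= 3 paired samples")
    rho = float(stats.spearmanr(conc, abund).statistic)
    return kappa, p, rho


@dataclass
class GeeFit:
    """Gaussian GEE fit with robust (sandwich) covariance."""

    params: pd.Series
    robust_se: pd.Series
    wald_z: pd.Series
    p_values: pd.Series
    working_rho: float
    result: object  # underlying statsmodels result

    def wald_test(self, constraint: str):
        """Wald test of a linear hypothesis, e.g. 'x1 + x2 = 0'."""
        return self.result.t_test(constraint)


def gee_fit(
    y,
    design: pd.DataFrame,
    clusters,
    corr: str = "exchangeable",
) -> GeeFit:
    """Gaussian GEE of a response on a design frame with clustered samples.

    ``design`` columns are used as patsy-free numeric/dummy regressors; an
    intercept is added.  ``clusters`` partitions observations (e.g. the
    patient); with all singleton clusters the estimates coincide with OLS.
    """
    design = pd.get_dummies(pd.DataFrame(design), drop_first=True, dtype=float)
    x = sm.add_constant(design, has_constant="add")
    cov = {
        "exchangeable": sm.cov_struct.Exchangeable(),
        "independence": sm.cov_struct.Independence(),
    }[corr]
    model = sm.GEE(
        np.asarray(y, float),
        x,
        groups=np.asarray(clusters),
        family=sm.families.Gaussian(),
        cov_struct=cov,
    )
    res = model.fit(maxiter=100, ctol=1e-8)
    params = pd.Series(res.params, index=x.columns)
    se = pd.Series(res.bse, index=x.columns)
    z = params / se
    p = pd.Series(2 * stats.norm.sf(np.abs(z)), index=x.columns)
    rho = float(cov.dep_params) if corr == "exchangeable" else 0.0
    return GeeFit(params, se, z, p, rho, res)
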