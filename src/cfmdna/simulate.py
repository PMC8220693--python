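"""Seeded synthetic cohorts with planted contaminants and true cfmDNA.

The generator emulates the statistical structure the decontamination
framework assumes, without modelling reads or chimeras:

* a "kitome" of reagent contaminants shared across extraction batches,
  with per-batch log-normal abundance multipliers (the source of
  batch effects), plus batch-specific contaminants present only in one
  batch's samples *and* its DENCs;
* sparse, low-abundance true plasma ASVs carried by a subset of
  patients, never present in any DENC, and replicated (minus a
  detection dropout) when the same patients are re-extracted in a
  replicate batch;
* log-normal sequencing depth and multinomial read sampling.

Ground truth labels per ASV enable recovery scoring of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import AsvCountTable, StudyDesign, TaxonomyTable

#: genera recurrently reported as reagent/laboratory contaminants
KITOME_GENERA = (
    "Ralstonia", "Burkholderia", "Pseudomonas", "Bradyrhizobium", "Comamonas",
    "Cupriavidus", "Sphingomonas", "Methylobacterium", "Acinetobacter",
    "Delftia", "Stenotrophomonas", "Herbaspirillum", "Mesorhizobium",
    "Phyllobacterium", "Variovorax", "Aquabacterium", "Pelomonas",
)

#: genera with documented commensal/pathogen evidence in high-biomass sites
COMMENSAL_GENERA = (
    "Faecalibacterium", "Bacteroides", "Ruminococcus", "Blautia",
    "Veillonella", "Streptococcus", "Prevotella", "Lactobacillus",
    "Clostridium", "Akkermansia", "Dorea", "Roseburia",
)

#: kitome genera that are also documented opportunistic pathogens; a
#: literature search finds evidence for them, so the taxonomy filter
#: alone cannot discard them — the statistical criteria must
DUAL_USE_GENERA = ("Pseudomonas", "Acinetobacter", "Stenotrophomonas", "Burkholderia")

_PHYLA = ("Proteobacteria", "Firmicutes", "Bacteroidetes", "Actinobacteria")


@dataclass
class BatchConfig:
    name: str
    n_samples: int = 12
    n_dencs: int = 8
    sequencing_run: str = "run1"
    n_days: int = 2
    replicate_of: str | None = None


@dataclass
class SimConfig:
    """Study conditions of the default synthetic cohort.

    Defaults mirror the framework's target design: five extraction
    batches of 12 plasma + 8 DENC samples, one replicate batch pair,
    200 reagent contaminants (a quarter batch-specific), and 20 true
    plasma ASVs planted at 0.1-1% relative abundance in 60% of patients
    with a 10% per-sample detection dropout.
    """

    batches: list = field(default_factory=lambda: [
        BatchConfig("A", sequencing_run="run1"),
        BatchConfig("B", sequencing_run="run1", replicate_of="A"),
        BatchConfig("C", sequencing_run="run2"),
        BatchConfig("D", sequencing_run="run2"),
        BatchConfig("E", sequencing_run="run2"),
    ])
    n_contaminant_asvs_shared: int = 150
    n_contaminant_asvs_batch_specific: int = 50
    n_true_asvs: int = 20
    true_prevalence: float = 0.6
    true_relabund_range: tuple = (1e-3, 1e-2)
    detection_dropout: float = 0.1
    depth_lognormal: tuple = (np.log(3e4), 0.3)
    contaminant_sigma: float = 1.5
    batch_effect_sigma: float = 1.0
    #: fraction of the shared kitome that is batch-stable (ubiquitous
    #: water/plasticware taxa with only a weak lot dependence); these evade
    #: the batch-effect screen and must be caught by the prevalence
    #: criterion, mirroring the real structure in which criterion (i)
    #: alone leaves many contaminants standing
    stable_contaminant_fraction: float = 0.5
    stable_batch_sigma: float = 0.1
    uncharacterised_fraction: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        names = {b.name for b in self.batches}
        for b in self.batches:
            if b.replicate_of is not None and b.replicate_of not in names:
                raise ValueError(f"replicate_of {b.replicate_of!r} is not a batch")
        for frac in (self.true_prevalence, self.detection_dropout,
                     self.uncharacterised_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        lo, hi = self.true_relabund_range
        if self.n_true_asvs * hi >= 1:
            raise ValueError("true-ASV abundance mass would exceed the composition")


@dataclass
class SimTruth:
    """Ground truth: per-ASV label, source batches and expected abundances."""

    labels: pd.Series                 # asv_id -> {true_signal, contaminant_shared, contaminant_batch}
    source_batches: pd.Series         # asv_id -> frozenset of batch names
    expected: pd.DataFrame            # expected relative abundance, ASV x sample

    def true_asvs(self) -> list:
        return list(self.labels.index[self.labels == "true_signal"])

    def contaminant_asvs(self) -> list:
        return list(self.labels.index[self.labels != "true_signal"])


def _lineage(genus: str, phylum: str) -> dict:
    return {
        "domain": "Bacteria",
        "phylum": phylum,
        "class": f"{phylum}_cl",
        "order": f"{genus}ales",
        "family": f"{genus}aceae",
        "genus": genus,
    }


def _order_only_lineage(phylum: str, tag: str) -> dict:
    return {
        "domain": "Bacteria",
        "phylum": phylum,
        "class": f"{phylum}_cl",
        "order": f"Uncultured_{tag}",
        "family": "",
        "genus": "",
    }


def default_evidence_lists():
    """Blocklist/evidence tables matching the simulator's genus pools."""
    from .taxon_filter import EvidenceLists

    block = pd.DataFrame({"name": KITOME_GENERA, "rank": "genus", "source": "kitome survey"})
    ev = pd.DataFrame(
        {
            "name": COMMENSAL_GENERA + DUAL_USE_GENERA,
            "rank": "genus",
            "source": ["commensal literature"] * len(COMMENSAL_GENERA)
            + ["opportunistic pathogen literature"] * len(DUAL_USE_GENERA),
        }
    )
    return EvidenceLists.from_frames(block, ev)


def simulate_cohort(cfg: SimConfig) -> tuple[AsvCountTable, StudyDesign, TaxonomyTable, SimTruth]:
    """Generate a full synthetic cohort; deterministic for a fixed config."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    batch_by_name = {b.name: b for b in cfg.batches}

    # --- patients: replicate batches reuse the parent's patient roster
    patients_of: dict[str, list[str]] = {}
    counter = 0
    for b in cfg.batches:
        if b.replicate_of is not None:
            parent = batch_by_name[b.replicate_of]
            if parent.n_samples != b.n_samples:
                raise ValueError("replicate batch must match its parent's sample count")
            patients_of[b.name] = patients_of[b.replicate_of]
        else:
            patients_of[b.name] = [f"P{counter + i:03d}" for i in range(b.n_samples)]
            counter += b.n_samples
    all_patients = sorted({p for ps in patients_of.values() for p in ps})

    # --- design rows
    rows = []
    for b in cfg.batches:
        days = [f"{b.name}_d{k + 1}" for k in range(b.n_days)]
        for j, patient in enumerate(patients_of[b.name]):
            rep = f"rg_{patient}" if (b.replicate_of is not None or any(
                bb.replicate_of == b.name for bb in cfg.batches)) else None
            rows.append({
                "sample_id": f"{b.name}_s{j + 1:02d}",
                "sample_type": "plasma",
                "patient_id": patient,
                "sequencing_run": b.sequencing_run,
                "extraction_batch": b.name,
                "extraction_day": days[j % b.n_days],
                "replicate_group": rep,
            })
        for j in range(b.n_dencs):
            rows.append({
                "sample_id": f"{b.name}_n{j + 1:02d}",
                "sample_type": "plasma_denc",
                "patient_id": None,
                "sequencing_run": b.sequencing_run,
                "extraction_batch": b.name,
                "extraction_day": days[j % b.n_days],
                "replicate_group": None,
            })
    design = StudyDesign(pd.DataFrame(rows))
    frame = design.frame
    sample_ids = list(frame.index)
    n_samples = len(sample_ids)

    # --- ASV roster
    shared_ids = [f"kit_s{i:03d}" for i in range(cfg.n_contaminant_asvs_shared)]
    batch_specific: dict[str, str] = {}
    bs_ids = []
    for i in range(cfg.n_contaminant_asvs_batch_specific):
        b = cfg.batches[i % len(cfg.batches)].name
        asv = f"kit_{b}_{i:03d}"
        bs_ids.append(asv)
        batch_specific[asv] = b
    true_ids = [f"true_{i:03d}" for i in range(cfg.n_true_asvs)]
    asv_ids = shared_ids + bs_ids + true_ids
    n_asv = len(asv_ids)
    asv_pos = {a: i for i, a in enumerate(asv_ids)}

    # --- contaminant base weights and per-batch multipliers
    base = rng.lognormal(0.0, cfg.contaminant_sigma, size=len(shared_ids) + len(bs_ids))
    batch_names = [b.name for b in cfg.batches]
    n_stable = int(round(cfg.stable_contaminant_fraction * len(shared_ids)))
    sigma_per_asv = np.full(len(base), cfg.batch_effect_sigma)
    sigma_per_asv[:n_stable] = cfg.stable_batch_sigma  # first shared block is batch-stable
    mult = {
        b: rng.lognormal(0.0, sigma_per_asv)
        for b in batch_names
    }
    # batch-specific contaminants vanish outside their own batch
    bs_mask = np.zeros((len(batch_names), len(base)))
    for bi, b in enumerate(batch_names):
        m = np.ones(len(base))
        for asv in bs_ids:
            if batch_specific[asv] != b:
                m[asv_pos[asv]] = 0.0
        bs_mask[bi] = m

    # --- true-ASV carriers and abundances
    lo, hi = cfg.true_relabund_range
    true_relabund = np.exp(rng.uniform(np.log(lo), np.log(hi), size=cfg.n_true_asvs))
    carriers = {
        t: {p for p in all_patients if rng.random() < cfg.true_prevalence}
        for t in true_ids
    }

    # --- expected relative abundance per sample
    expected = np.zeros((n_asv, n_samples))
    for si, sid in enumerate(sample_ids):
        b = frame.loc[sid, "extraction_batch"]
        bi = batch_names.index(b)
        contam = base * mult[b] * bs_mask[bi]
        true_mass = np.zeros(cfg.n_true_asvs)
        if frame.loc[sid, "sample_type"] == "plasma":
            patient = frame.loc[sid, "patient_id"]
            for ti, t in enumerate(true_ids):
                if patient in carriers[t] and rng.random() >= cfg.detection_dropout:
                    true_mass[ti] = true_relabund[ti]
        total_true = float(true_mass.sum())
        p = np.zeros(n_asv)
        p[: len(base)] = contam / contam.sum() * (1.0 - total_true)
        p[len(base):] = true_mass
        expected[:, si] = p

    # --- reads
    mu, sigma = cfg.depth_lognormal
    depths = np.maximum(rng.lognormal(mu, sigma, size=n_samples), 100).astype(int)
    counts = np.zeros((n_asv, n_samples), dtype=np.int64)
    for si in range(n_samples):
        counts[:, si] = rng.multinomial(depths[si], expected[:, si])
    table = AsvCountTable(pd.DataFrame(counts, index=asv_ids, columns=sample_ids))

    # --- taxonomy from the configurable name pools
    tax_rows = []
    for i, asv in enumerate(shared_ids + bs_ids):
        if rng.random() < cfg.uncharacterised_fraction:
            lin = _order_only_lineage(_PHYLA[i % len(_PHYLA)], f"kit{i}")
        else:
            lin = _lineage(KITOME_GENERA[i % len(KITOME_GENERA)], _PHYLA[i % len(_PHYLA)])
        tax_rows.append({"asv_id": asv, **lin})
    for i, asv in enumerate(true_ids):
        if rng.random() < cfg.uncharacterised_fraction:
            lin = _order_only_lineage("Firmicutes", f"true{i}")
        else:
            lin = _lineage(COMMENSAL_GENERA[i % len(COMMENSAL_GENERA)], "Firmicutes")
        tax_rows.append({"asv_id": asv, **lin})
    taxonomy = TaxonomyTable(pd.DataFrame(tax_rows))

    # --- truth
    labels = pd.Series(
        ["contaminant_shared"] * len(shared_ids)
        + ["contaminant_batch"] * len(bs_ids)
        + ["true_signal"] * len(true_ids),
        index=asv_ids,
    )
    source = pd.Series(
        [frozenset(batch_names)] * len(shared_ids)
        + [frozenset({batch_specific[a]}) for a in bs_ids]
        + [frozenset()] * len(true_ids),
        index=asv_ids,
    )
    truth = SimTruth(labels, source, pd.DataFrame(expected, index=asv_ids, columns=sample_ids))

    # structural assertions on the construction itself
    denc_cols = design.samples_of_type("plasma_denc")
    assert (table.counts.loc[true_ids, denc_cols].to_numpy() == 0).all(), \
        "true-signal ASV observed in a DENC"
    for asv, b in batch_specific.items():
        outside = [s for s in sample_ids if frame.loc[s, "extraction_batch"] != b]
        assert (table.counts.loc[asv, outside].to_numpy() == 0).all(), \
            "batch-specific contaminant escaped its batch"
    return table, design, taxonomy, truth


def simulate_mock_community(
    n_strains: int = 20,
    bias_sigma: float = 1.0,
    n_runs: int = 2,
    depth: int = 100000,
    seed: int = 0,
    bias: np.ndarray | None = None,
) -> AsvCountTable:
    """Evenly mixed mock community with a fixed per-strain PCR bias.

    Equal true proportions are multiplied by one log-normal bias vector
    shared across runs, so the observed (uneven) abundance profile is
    consistent between library preparations.  Passing an explicit
    ``bias`` vector (e.g. with one zero entry) emulates a dropped strain.
    """
    if n_strains < 2:
        raise ValueError("need at least two strains")
    rng = np.random.default_rng(seed)
    if bias is None:
        bias = rng.lognormal(0.0, bias_sigma, size=n_strains)
    bias = np.asarray(bias, float)
    p = bias / bias.sum() if bias.sum() > 0 else bias
    counts = {
        f"run{r + 1}": rng.multinomial(depth, p) for r in range(n_runs)
    }
    ids = [f"strain_{i + 1:02d}" for i in range(n_strains)]
    return AsvCountTable(pd.DataFrame(counts, index=ids))


def simulate_dilution_series(
    concentrations,
    contaminant_pool: int = 30,
    reads_at_max: int = 50000,
    contaminant_reads: int = 500,
    seed: int = 0,
) -> AsvCountTable:
    """Ten-fold-style dilution series of a single target organism.

    Expected target reads scale with concentration below a saturation
    plateau at ``reads_at_max``; contaminant reads are constant in
    expectation, so the contaminant proportion rises as the target is
    diluted out.
    """
    conc = np.asarray(list(concentrations), float)
    if np.any(conc <= 0) or np.any(np.diff(conc) >= 0):
        raise ValueError("concentrations must be positive and strictly descending")
    rng = np.random.default_rng(seed)
    # linear response saturating one decade below the top concentration
    scale = reads_at_max / (conc[0] / 10.0)
    weights = rng.lognormal(0.0, 1.0, size=contaminant_pool) if contaminant_pool else np.array([])
    cols = {}
    for i, c in enumerate(conc):
        target = rng.poisson(min(reads_at_max, scale * c))
        if contaminant_pool:
            contam = rng.multinomial(rng.poisson(contaminant_reads), weights / weights.sum())
        else:
            contam = np.zeros(0, dtype=int)
        cols[f"dil_{i}"] = np.concatenate([[target], contam])
    ids = ["target"] + [f"contam_{j:02d}" for j in range(contaminant_pool)]
    return AsvCountTable(pd.DataFrame(cols, index=ids))


def evaluate_recovery(truth: SimTruth, final_list) -> tuple[float, float, pd.DataFrame]:
    """Score a recovered ASV list against the simulation's ground truth.

    Returns (sensitivity, false_pass_rate, confusion) where sensitivity
    is the recovered fraction of true-signal ASVs, false_pass_rate the
    contaminant fraction within the final list, and confusion a per-label
    tally of recovered vs missed ASVs.
    """
    final = set(final_list)
    unknown = final - set(truth.labels.index)
    if unknown:
        raise ValueError(f"ASVs outside the simulated table: {sorted(unknown)[:5]}")
    true_set = set(truth.true_asvs())
    sensitivity = len(final & true_set) / len(true_set) if true_set else float("nan")
    false_pass = (len(final - true_set) / len(final)) if final else 0.0
    rows = []
    for label in ("true_signal", "contaminant_shared", "contaminant_batch"):
        members = set(truth.labels.index[truth.labels == label])
        rows.append({
            "label": label,
            "total": len(members),
            "recovered": len(members & final),
            "missed": len(members - final),
        })
    return sensitivity, false_pass, pd.DataFrame(rows).set_index("label")
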