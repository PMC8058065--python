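"""Synthetic study generator with known ground truth.

Emulates the statistical structure of a tumor-organoid epigenome study:
10 tumor + 5 normal chromatin-state segmentations over a toy genome with
planted gained/lost enhancers, negative-binomial H3K27ac counts with a
configurable fold-change effect, conservation-tiered TF binding, a
pan-accessible enhancer block across several pseudo cancer types, and a
labelled single-cell expression matrix whose malignant cells over-express a
signature gene set.

The toy genome is built from 20-kb cassettes. Each cassette holds (at most)
one gene — TSS with active-promoter states around it — three enhancer slots
placed > 5 kb from every TSS, and fixed filler segments so that all eight
chromatin states occur; everything else is quiescent. Planted enhancers
occupy slots with identical coordinates in every carrier sample, so the
consensus regions recovered by the cataloguing pipeline coincide exactly
with the planted truth intervals.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .catalog import StateSegmentation
from .differential import CountMatrix
from .intervals import GenomeLayout, GenomicInterval, IntervalSet
from .pancancer import AccessibilityMatrix

CASSETTE = 20_000
SLOT_OFFSETS = (7_200, 10_500, 13_800)  # all > 5 kb + promoter margin from TSS
TSS_OFFSET = 2_000

CANCER_TYPE_NAMES = ("COAD", "BRCA", "LUAD", "LIHC", "PRAD", "STAD", "KIRC", "GBM")

POPULATIONS = ("malignant", "normal_epithelial", "B", "T", "myeloid", "mast", "stromal")


@dataclass
class CohortConfig:
    # genome
    n_chromosomes: int = 10
    chrom_length: int = 400_000
    n_genes: int = 200
    # cohort
    n_tumor: int = 10
    n_normal: int = 5
    # planted regions
    n_planted_gained: int = 60
    n_planted_lost: int = 20
    n_background: int = 400
    n_decoys: int = 30
    n_singletons: int = 10
    conservation_profile: tuple[int, ...] | None = None  # carriers per gained enhancer
    # H3K27ac counts
    effect_size: float = 8.0
    nb_dispersion: float = 0.1
    base_mean: float = 100.0
    # TF binding probability per conservation tier (carrier fraction)
    tf_prob_background: float = 0.1
    tf_prob_mid: float = 0.25
    tf_prob_top: float = 0.4
    # pan-cancer accessibility panel
    n_cancer_types: int = 6
    samples_per_type: int = 4
    pan_fraction: float = 0.23
    atac_high: float = 5.0
    atac_low: float = 0.0
    atac_sd: float = 0.5
    # single cell
    n_malignant: int = 500
    n_normal_epithelial: int = 500
    n_other: int = 500
    signature_size: int = 30
    overexpression: float = 4.0
    sc_base_rate: float = 0.5
    sc_library_sigma: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_planted_gained,
            self.n_planted_lost,
            self.n_background,
            self.n_decoys,
            self.n_singletons,
            self.n_tumor,
            self.n_normal,
            self.n_genes,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0")
        for p in (self.tf_prob_background, self.tf_prob_mid, self.tf_prob_top,
                  self.pan_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_planted_gained > 0 and self.n_tumor < 2:
            raise ValueError(
                "planted gained enhancers need >= 2 tumor samples to satisfy "
                "the 2-sample consensus rule"
            )

    @property
    def n_cassettes(self) -> int:
        return self.n_chromosomes * (self.chrom_length // CASSETTE)

    @property
    def n_slots(self) -> int:
        return self.n_cassettes * len(SLOT_OFFSETS)


@dataclass
class GroundTruth:
    enhancers: pd.DataFrame  # region_id, coords, label, carriers, flags, linked gene
    cell_labels: pd.Series
    signature_genes: list[str]
    stemness_genes: list[str]

    def of_label(self, label: str) -> IntervalSet:
        sub = self.enhancers[self.enhancers["label"] == label]
        return IntervalSet(
            [
                GenomicInterval(r.chrom, int(r.start), int(r.end))
                for r in sub.itertuples()
            ]
        )


@dataclass
class CohortBundle:
    config: CohortConfig
    genome: GenomeLayout
    genes: pd.DataFrame
    segmentations: dict[str, StateSegmentation]
    counts: CountMatrix
    tf_peaks: IntervalSet
    atac_peaks: IntervalSet
    accessibility: AccessibilityMatrix
    interactions: pd.DataFrame
    cell_matrix: pd.DataFrame
    cell_labels: pd.Series
    truth: GroundTruth


# --------------------------------------------------------------- NB counts

def sample_negative_binomial(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB(mean mu, dispersion alpha) with variance mu + alpha * mu^2.

    Gamma-Poisson mixture; dispersion 0 degenerates to Poisson.
    """
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def simulate_counts(
    n_regions: int = 2000,
    n_planted: int = 60,
    effect_size: float = 8.0,
    dispersion: float = 0.1,
    n_tumor: int = 10,
    n_normal: int = 5,
    base_mean: float = 100.0,
    rng_seed: int = 0,
) -> tuple[CountMatrix, np.ndarray]:
    """Region x sample NB count matrix with the first ``n_planted`` regions
    boosted ``effect_size``-fold in every tumor sample.

    Returns the matrix and a boolean planted-region mask.
    """
    rng = np.random.default_rng(rng_seed)
    samples = [f"T{i + 1:02d}" for i in range(n_tumor)] + [
        f"N{i + 1:02d}" for i in range(n_normal)
    ]
    groups = {s: ("tumor" if s.startswith("T") else "normal") for s in samples}
    base = rng.lognormal(mean=np.log(base_mean), sigma=0.5, size=n_regions)
    planted = np.zeros(n_regions, dtype=bool)
    planted[:n_planted] = True
    means = np.tile(base[:, None], (1, len(samples)))
    means[planted, :n_tumor] *= effect_size
    counts = sample_negative_binomial(rng, means, dispersion)
    df = pd.DataFrame(
        counts,
        index=[f"chr1:{i * 1000}-{i * 1000 + 500}" for i in range(n_regions)],
        columns=samples,
    )
    return CountMatrix(df, groups), planted


def simulate_accessibility_panel(
    n_rows: int = 100,
    pan_fraction: float = 0.23,
    n_types: int = 6,
    samples_per_type: int = 4,
    high: float = 5.0,
    low: float = 0.0,
    sd: float = 0.5,
    rng_seed: int = 0,
) -> tuple[AccessibilityMatrix, np.ndarray]:
    """Two-block enhancer x sample panel with a planted pan-accessible block.

    Pan rows are high in every cancer type; the rest are high only in the
    first (colon-like) type. Returns the matrix and the pan-row mask.
    """
    rng = np.random.default_rng(rng_seed)
    types = list(CANCER_TYPE_NAMES[:n_types])
    samples = [f"{t}_{j + 1}" for t in types for j in range(samples_per_type)]
    sample_types = {s: s.rsplit("_", 1)[0] for s in samples}
    n_pan = int(round(pan_fraction * n_rows))
    pan_mask = np.zeros(n_rows, dtype=bool)
    pan_mask[rng.choice(n_rows, size=n_pan, replace=False)] = True
    mu = np.full((n_rows, len(samples)), low)
    for c, s in enumerate(samples):
        colon_like = sample_types[s] == types[0]
        mu[:, c] = np.where(pan_mask | colon_like, high, low)
    values = rng.normal(mu, sd)
    matrix = AccessibilityMatrix(
        pd.DataFrame(
            values,
            index=[f"enh_{i + 1:04d}" for i in range(n_rows)],
            columns=samples,
        ),
        sample_types,
    )
    return matrix, pan_mask


# ------------------------------------------------------------ cohort proper

def _tier_of(carrier_fraction: float) -> str:
    if carrier_fraction >= 0.8:
        return "top"
    if carrier_fraction >= 0.5:
        return "mid"
    return "background"


def simulate_cohort(config: CohortConfig) -> CohortBundle:
    rng = np.random.default_rng(config.rng_seed)
    genome = GenomeLayout(
        {f"chr{i + 1}": config.chrom_length for i in range(config.n_chromosomes)}
    )

    # -- gene annotation: one gene per cassette, first n_genes cassettes
    per_chrom = config.chrom_length // CASSETTE
    if config.n_genes > config.n_cassettes:
        raise ValueError("n_genes exceeds available cassettes")
    genes_rows = []
    cassette_gene: dict[int, str] = {}
    for g in range(config.n_genes):
        chrom_i, cass_i = divmod(g, per_chrom)
        gene_id = f"G{g + 1:04d}"
        genes_rows.append(
            {
                "gene_id": gene_id,
                "chrom": f"chr{chrom_i + 1}",
                "tss": cass_i * CASSETTE + TSS_OFFSET,
                "strand": "+" if g % 2 == 0 else "-",
                "biotype": "protein_coding" if g % 10 else "lincRNA",
            }
        )
        cassette_gene[g] = gene_id
    genes = pd.DataFrame(genes_rows)

    # -- allocate enhancer slots
    n_entities = (
        config.n_planted_gained
        + config.n_planted_lost
        + config.n_background
        + config.n_decoys
        + config.n_singletons
    )
    if n_entities > config.n_slots:
        raise ValueError(
            f"{n_entities} planted regions exceed {config.n_slots} slots; "
            "enlarge the genome"
        )
    slot_order = rng.permutation(config.n_slots)[:n_entities]
    labels = (
        ["gained"] * config.n_planted_gained
        + ["lost"] * config.n_planted_lost
        + ["background"] * config.n_background
        + ["decoy"] * config.n_decoys
        + ["singleton"] * config.n_singletons
    )

    tumor_samples = [f"T{i + 1:02d}" for i in range(config.n_tumor)]
    normal_samples = [f"N{i + 1:02d}" for i in range(config.n_normal)]
    all_samples = tumor_samples + normal_samples

    profile = config.conservation_profile
    if profile is None and config.n_planted_gained:
        cycle = list(range(2, config.n_tumor + 1)) or [config.n_tumor]
        profile = tuple(
            cycle[i % len(cycle)] for i in range(config.n_planted_gained)
        )
    profile = profile or ()
    if len(profile) not in (0, config.n_planted_gained):
        raise ValueError("conservation_profile length must equal n_planted_gained")
    if any(not 2 <= k <= config.n_tumor for k in profile):
        raise ValueError("carrier counts must lie in [2, n_tumor]")

    truth_rows = []
    gained_i = 0
    for slot, label in zip(slot_order, labels):
        cassette_i, slot_j = divmod(int(slot), len(SLOT_OFFSETS))
        chrom_i, cass_i = divmod(cassette_i, per_chrom)
        chrom = f"chr{chrom_i + 1}"
        base = cass_i * CASSETTE + SLOT_OFFSETS[slot_j]
        if label == "decoy":
            length = int(rng.integers(100, 181))
        else:
            length = int(rng.integers(400, 2001))
        start = base + int(rng.integers(0, 101))
        end = start + length
        if label == "gained":
            k = profile[gained_i]
            gained_i += 1
            carriers = list(rng.choice(tumor_samples, size=k, replace=False))
        elif label == "lost":
            carriers = list(normal_samples)
        elif label == "singleton":
            carriers = [tumor_samples[int(rng.integers(config.n_tumor))]]
        else:  # background and decoy: everywhere
            carriers = list(all_samples)
        linked = cassette_gene.get(cassette_i)
        truth_rows.append(
            {
                "region_id": f"{chrom}:{start}-{end}",
                "chrom": chrom,
                "start": start,
                "end": end,
                "label": label,
                "carriers": ",".join(sorted(carriers)),
                "n_carriers": len(carriers),
                "n_tumor_carriers": sum(c in tumor_samples for c in carriers),
                "linked_gene": linked if linked is not None else "",
            }
        )
    truth = pd.DataFrame(truth_rows)

    # -- per-sample segmentations (partition of every chromosome)
    segmentations = {}
    for sample in all_samples:
        features: dict[str, list[tuple[int, int, str]]] = {
            c: [] for c in genome.chromosomes
        }
        for _, g in genes.iterrows():
            tss = int(g["tss"])
            features[g["chrom"]] += [
                (tss - 1000, tss - 200, "FlnkActTSS"),
                (tss - 200, tss + 200, "ActTSS"),
                (tss + 200, tss + 1000, "FlnkActTSS"),
            ]
        for cassette_i in range(config.n_cassettes):
            chrom_i, cass_i = divmod(cassette_i, per_chrom)
            off = cass_i * CASSETTE
            features[f"chr{chrom_i + 1}"] += [
                (off + 17_000, off + 17_500, "WkEnh"),
                (off + 17_500, off + 18_500, "Elong"),
                (off + 18_500, off + 19_500, "Repr"),
            ]
        for i, row in truth.iterrows():
            if sample in row["carriers"].split(","):
                state = "ActEnh" if i % 2 == 0 else "FlnkActEnh"
                features[row["chrom"]].append((row["start"], row["end"], state))
        segments = []
        for chrom, feats in features.items():
            feats.sort()
            pos = 0
            for s, e, state in feats:
                if s > pos:
                    segments.append(GenomicInterval(chrom, pos, s, name="Quiescent"))
                segments.append(GenomicInterval(chrom, s, e, name=state))
                pos = e
            if pos < genome.length(chrom):
                segments.append(
                    GenomicInterval(chrom, pos, genome.length(chrom), name="Quiescent")
                )
        segmentations[sample] = StateSegmentation(sample, IntervalSet(segments))

    # -- H3K27ac counts over consensus-eligible regions (>= 2 carriers, >=200bp)
    count_rows = truth[truth["label"].isin(["gained", "lost", "background"])]
    base = rng.lognormal(
        mean=np.log(config.base_mean), sigma=0.5, size=len(count_rows)
    )
    means = np.tile(base[:, None], (1, len(all_samples)))
    for r, (_, row) in enumerate(count_rows.iterrows()):
        carriers = set(row["carriers"].split(","))
        if row["label"] == "gained":
            for s, sample in enumerate(all_samples):
                if sample in carriers and sample in tumor_samples:
                    means[r, s] *= config.effect_size
        elif row["label"] == "lost":
            for s, sample in enumerate(all_samples):
                if sample in normal_samples:
                    means[r, s] *= config.effect_size
    counts_arr = sample_negative_binomial(rng, means, config.nb_dispersion)
    counts = CountMatrix(
        pd.DataFrame(
            counts_arr, index=list(count_rows["region_id"]), columns=all_samples
        ),
        {s: ("tumor" if s in tumor_samples else "normal") for s in all_samples},
    )

    # -- TF peaks with conservation-tier-dependent binding probability
    tier_prob = {
        "top": config.tf_prob_top,
        "mid": config.tf_prob_mid,
        "background": config.tf_prob_background,
    }
    tf_bound = []
    tf_peaks = []
    for _, row in truth.iterrows():
        if row["label"] == "gained":
            frac = row["n_tumor_carriers"] / config.n_tumor
            p = tier_prob[_tier_of(frac)]
        elif row["label"] == "background":
            p = config.tf_prob_background
        else:
            p = 0.0
        bound = bool(rng.random() < p)
        tf_bound.append(bound)
        if bound:
            width = min(300, row["end"] - row["start"])
            s = row["start"] + (row["end"] - row["start"] - width) // 2
            tf_peaks.append(
                GenomicInterval(
                    row["chrom"], int(s), int(s + width),
                    name=f"TAZ_{row['region_id']}",
                    score=float(rng.lognormal(2.0, 0.5)),
                    summit=width // 2,
                )
            )
    truth["tf_bound"] = tf_bound
    tf_peak_set = IntervalSet(tf_peaks)

    # -- ATAC peaks: open chromatin at TF-bound enhancers and gene promoters
    atac_peaks = []
    for _, row in truth[truth["tf_bound"]].iterrows():
        width = min(400, row["end"] - row["start"])
        s = row["start"] + (row["end"] - row["start"] - width) // 2
        atac_peaks.append(
            GenomicInterval(
                row["chrom"], int(s), int(s + width),
                name=f"ATAC_{row['region_id']}",
                score=float(rng.lognormal(2.0, 0.5)),
                summit=width // 2,
            )
        )
        if rng.random() < 0.3:  # secondary, weaker peak
            atac_peaks.append(
                GenomicInterval(
                    row["chrom"], int(row["start"]), int(row["start"]) + 200,
                    name=f"ATAC2_{row['region_id']}",
                    score=float(rng.lognormal(0.5, 0.3)),
                    summit=100,
                )
            )
    for _, g in genes.iterrows():
        tss = int(g["tss"])
        atac_peaks.append(
            GenomicInterval(
                g["chrom"], tss - 150, tss + 150,
                name=f"ATAC_{g['gene_id']}",
                score=float(rng.lognormal(2.0, 0.5)),
                summit=150,
            )
        )
    atac_peak_set = IntervalSet(atac_peaks)

    # -- pan-cancer accessibility panel over TF-bound gained enhancers
    panel = truth[(truth["label"] == "gained") & truth["tf_bound"]]
    n_pan = int(round(config.pan_fraction * len(panel)))
    pan_ids = set(
        rng.choice(panel["region_id"].to_numpy(), size=n_pan, replace=False)
        if n_pan
        else []
    )
    truth["pan_accessible"] = truth["region_id"].isin(pan_ids)
    types = list(CANCER_TYPE_NAMES[: config.n_cancer_types])
    atac_samples = [
        f"{t}_{j + 1}" for t in types for j in range(config.samples_per_type)
    ]
    sample_types = {s: s.rsplit("_", 1)[0] for s in atac_samples}
    acc = np.empty((len(panel), len(atac_samples)))
    for r, rid in enumerate(panel["region_id"]):
        for c, s in enumerate(atac_samples):
            colon_like = sample_types[s] == types[0]
            high = rid in pan_ids or colon_like
            mu = config.atac_high if high else config.atac_low
            acc[r, c] = rng.normal(mu, config.atac_sd)
    accessibility = AccessibilityMatrix(
        pd.DataFrame(acc, index=list(panel["region_id"]), columns=atac_samples),
        sample_types,
    )

    # -- enhancer-promoter interaction map for half the gained enhancers
    inter_rows = []
    for _, row in truth[truth["label"] == "gained"].iterrows():
        if row["linked_gene"] and rng.random() < 0.5:
            inter_rows.append(
                {
                    "chrom": row["chrom"],
                    "start": row["start"],
                    "end": row["end"],
                    "gene_id": row["linked_gene"],
                }
            )
    interactions = pd.DataFrame(
        inter_rows, columns=["chrom", "start", "end", "gene_id"]
    )

    # -- single-cell matrix: malignant cells over-express the signature set
    gene_ids = list(genes["gene_id"])
    linked_coding = [
        g
        for g in truth.loc[truth["label"] == "gained", "linked_gene"]
        if g and genes.set_index("gene_id").loc[g, "biotype"] == "protein_coding"
    ]
    signature = list(dict.fromkeys(linked_coding))[: config.signature_size]
    remaining = [g for g in gene_ids if g not in signature]
    stemness = remaining[: config.signature_size]
    n_cells = config.n_malignant + config.n_normal_epithelial + config.n_other
    cell_labels = pd.Series(
        ["malignant"] * config.n_malignant
        + ["normal_epithelial"] * config.n_normal_epithelial
        + ["stromal"] * config.n_other,
        index=[f"cell_{i + 1:05d}" for i in range(n_cells)],
        name="label",
    )
    gene_rate = rng.lognormal(np.log(config.sc_base_rate), 0.5, size=len(gene_ids))
    lib = rng.lognormal(0.0, config.sc_library_sigma, size=n_cells)
    rates = np.outer(lib, gene_rate)
    sig_idx = [gene_ids.index(g) for g in signature]
    malignant_mask = (cell_labels == "malignant").to_numpy()
    rates[np.ix_(malignant_mask, sig_idx)] *= config.overexpression
    cell_matrix = pd.DataFrame(
        rng.poisson(rates), index=cell_labels.index, columns=gene_ids
    )

    ground_truth = GroundTruth(
        enhancers=truth,
        cell_labels=cell_labels,
        signature_genes=signature,
        stemness_genes=stemness,
    )
    return CohortBundle(
        config=config,
        genome=genome,
        genes=genes,
        segmentations=segmentations,
        counts=counts,
        tf_peaks=tf_peak_set,
        atac_peaks=atac_peak_set,
        accessibility=accessibility,
        interactions=interactions,
        cell_matrix=cell_matrix,
        cell_labels=cell_labels,
        truth=ground_truth,
    )


# ----------------------------------------------------------------- fixtures

def write_fixture(bundle: CohortBundle, directory: str | Path) -> None:
    """Write the bundle in the pipeline's external text formats."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    eio.write_chrom_sizes(bundle.genome, d / "chrom.sizes")
    eio.write_genes_tsv(bundle.genes, d / "genes.tsv")
    for sample, seg in bundle.segmentations.items():
        eio.write_segmentation_bed(seg.segments, d / f"seg_{sample}.bed")
    eio.write_counts_tsv(bundle.counts.counts, d / "counts.tsv")
    eio.write_groups_tsv(bundle.counts.groups, d / "groups.tsv")
    eio.write_narrowpeak(bundle.tf_peaks, d / "tf_peaks.narrowPeak")
    eio.write_narrowpeak(bundle.atac_peaks, d / "atac_peaks.narrowPeak")
    eio.write_matrix_tsv(bundle.accessibility.values, d / "accessibility.tsv")
    eio.write_groups_tsv(
        {s: t for s, t in bundle.accessibility.sample_types.items()},
        d / "sample_types.tsv",
    )
    eio.write_interactions(bundle.interactions, d / "interactions.bedpe")
    eio.write_cell_matrix(bundle.cell_matrix, bundle.cell_labels, d / "cells")
    bundle.truth.enhancers.to_csv(d / "truth_enhancers.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "gene_set": ["signature"] * len(bundle.truth.signature_genes)
            + ["stemness"] * len(bundle.truth.stemness_genes),
            "gene_id": bundle.truth.signature_genes + bundle.truth.stemness_genes,
        }
    ).to_csv(d / "truth_genesets.tsv", sep="\t", index=False)
    with open(d / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(bundle.config), fh, indent=1, default=list)


def load_fixture(directory: str | Path) -> CohortBundle:
    """Read a written fixture back into an equivalent bundle."""
    d = Path(directory)
    with open(d / "config.json") as fh:
        raw = json.load(fh)
    if raw.get("conservation_profile") is not None:
        raw["conservation_profile"] = tuple(raw["conservation_profile"])
    config = CohortConfig(**raw)
    genome = eio.read_chrom_sizes(d / "chrom.sizes")
    genes = eio.read_genes_tsv(d / "genes.tsv")
    segmentations = {}
    for path in sorted(d.glob("seg_*.bed")):
        sample = path.stem.removeprefix("seg_")
        segmentations[sample] = StateSegmentation(
            sample, eio.read_segmentation_bed(path)
        )
    counts = CountMatrix(
        eio.read_counts_tsv(d / "counts.tsv"), eio.read_groups_tsv(d / "groups.tsv")
    )
    accessibility = AccessibilityMatrix(
        eio.read_matrix_tsv(d / "accessibility.tsv"),
        eio.read_groups_tsv(d / "sample_types.tsv"),
    )
    cell_matrix, cell_labels = eio.read_cell_matrix(d / "cells")
    truth_df = pd.read_csv(
        d / "truth_enhancers.tsv", sep="\t", keep_default_na=False,
        dtype={"carriers": str, "linked_gene": str},
    )
    for col in ("tf_bound", "pan_accessible"):
        truth_df[col] = truth_df[col].astype(str) == "True"
    genesets = pd.read_csv(d / "truth_genesets.tsv", sep="\t")
    truth = GroundTruth(
        enhancers=truth_df,
        cell_labels=cell_labels,
        signature_genes=list(genesets.loc[genesets["gene_set"] == "signature", "gene_id"]),
        stemness_genes=list(genesets.loc[genesets["gene_set"] == "stemness", "gene_id"]),
    )
    return CohortBundle(
        config=config,
        genome=genome,
        genes=genes,
        segmentations=segmentations,
        counts=counts,
        tf_peaks=eio.read_narrowpeak(d / "tf_peaks.narrowPeak"),
        atac_peaks=eio.read_narrowpeak(d / "atac_peaks.narrowPeak"),
        accessibility=accessibility,
        interactions=eio.read_interactions(d / "interactions.bedpe"),
        cell_matrix=cell_matrix,
        cell_labels=cell_labels,
        truth=truth,
    )
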