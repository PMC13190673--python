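"""Paired metabarcoding/microscopy community simulator with ground truth.

The generator emulates the observation process of a brackish-to-marine
monitoring program spanning a strong salinity gradient:

* taxa carry Gaussian salinity niches, so basins with different
  salinities host distinct communities (the source of beta diversity);
* cell volumes are lognormal with class-specific medians, and the 18S
  marker copy number per cell follows a power law k = kappa * v**gamma
  of cell volume, which decouples read counts from cell counts;
* metabarcoding observes cells captured on the filter (Poisson in the
  filtered volume), shared spike/community extraction efficiency,
  per-taxon PCR bias, and multinomial sequencing including the spike-in
  reads; sequencing depth saturates with DNA yield so that very small
  filtered volumes return fewer reads;
* microscopy observes Poisson counts in a settling chamber with
  size-dependent detectability (small cells are missed) and
  identification blur (small cells are reported at order or class
  rank), with biovolume and carbon derived from the carbon model.

Everything is deterministic given (config, seed), and the unobserved
truth (cells/L, cell volume, copy number, molecules/L) is returned for
recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .biomass import CarbonModel, carbon_per_cell, group_for_class
from .io import AsvTable
from .normalize import spike_normalize
from .taxonomy import DIATOM_LUMP, RANKS, UNASSIGNED

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_truth",
    "simulate_metabarcoding",
    "simulate_microscopy",
    "simulate_replicate_study",
    "simulate_volume_scenario",
    "richness_totals",
    "simulate_dataset",
    "evaluate_spike_recovery",
    "CLASS_LINEAGES",
    "CLASS_MEDIAN_VOLUMES",
]

#: Supergroup/division/subdivision backbone per whitelist class.
CLASS_LINEAGES: dict[str, tuple[str, str, str]] = {
    "Bacillariophyceae": ("TSAR", "Stramenopiles", "Gyrista"),
    DIATOM_LUMP: ("TSAR", "Stramenopiles", "Gyrista"),
    "Chlorodendrophyceae": ("Archaeplastida", "Chlorophyta", "Chlorophytina"),
    "Chlorophyceae": ("Archaeplastida", "Chlorophyta", "Chlorophytina"),
    "Chrysophyceae": ("TSAR", "Stramenopiles", "Gyrista"),
    "Coccolithophyceae": ("Haptista", "Haptophyta", "Haptophytina"),
    "Cryptophyceae": ("Cryptista", "Cryptophyta", "Cryptophytina"),
    "Dictyochophyceae": ("TSAR", "Stramenopiles", "Gyrista"),
    "Dinophyceae": ("TSAR", "Alveolata", "Dinoflagellata"),
    "Eustigmatophyceae": ("TSAR", "Stramenopiles", "Gyrista"),
    "Noctilucophyceae": ("TSAR", "Alveolata", "Dinoflagellata"),
    "Pyramimonadophyceae": ("Archaeplastida", "Chlorophyta", "Chlorophytina"),
    "Raphidophyceae": ("TSAR", "Stramenopiles", "Gyrista"),
    "Trebouxiophyceae": ("Archaeplastida", "Chlorophyta", "Chlorophytina"),
}

#: Median cell volume (um^3) per class; nano- to microplankton range,
#: with large within-class spread on top (see SimulationConfig).
CLASS_MEDIAN_VOLUMES: dict[str, float] = {
    "Bacillariophyceae": 800.0,
    DIATOM_LUMP: 1500.0,
    "Chlorodendrophyceae": 150.0,
    "Chlorophyceae": 100.0,
    "Chrysophyceae": 150.0,
    "Coccolithophyceae": 90.0,
    "Cryptophyceae": 150.0,
    "Dictyochophyceae": 600.0,
    "Dinophyceae": 2000.0,
    "Eustigmatophyceae": 40.0,
    "Noctilucophyceae": 8000.0,
    "Pyramimonadophyceae": 250.0,
    "Raphidophyceae": 1500.0,
    "Trebouxiophyceae": 50.0,
}

BASIN_NAMES = ("Bothnian Bay", "Bothnian Sea", "Baltic Proper", "Kattegat", "Skagerrak")
BASIN_SALINITIES = (2.5, 5.0, 7.0, 21.5, 28.5)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and observation parameters of the simulator.

    Defaults mirror the monitoring design the package targets: five sea
    basins spanning salinity ~2-32, 200 ml filtered for DNA, a 25 ml
    settling chamber for microscopy, and a known number of spike-in
    molecules added to every sample before lysis.
    """

    basin_names: tuple[str, ...] = BASIN_NAMES
    basin_salinities: tuple[float, ...] = BASIN_SALINITIES
    stations_per_basin: int = 2
    samples_per_station: int = 2
    taxa_per_class: int = 3
    classes: tuple[str, ...] = tuple(sorted(CLASS_MEDIAN_VOLUMES))
    volume_sigma_log: float = 1.2          # ln-scale spread of cell volume
    depth: int = 100_000                   # nominal reads per sample
    spike_molecules: float = 2e8           # M, molecules added per sample (~2% of reads)
    n_spike_asvs: int = 2
    volume_filtered: float = 0.2           # liters
    volume_options: tuple[float, ...] = (0.01, 0.1, 0.2, 0.5)
    copy_kappa: float = 100.0              # k = kappa * v**gamma
    copy_gamma: float = 0.9
    niche_width_mean: float = 4.0          # salinity units
    niche_width_sd: float = 1.0
    niche_min: float = 1.0
    niche_max: float = 32.0
    abundance_median: float = 2e4          # cells/L at the niche optimum
    abundance_sigma_log: float = 1.5
    abundance_noise_cv: float = 0.3        # sample-level lognormal noise
    extraction_sigma: float = 0.3          # ln-scale, shared spike/community
    pcr_bias_sigma: float = 0.4            # ln-scale, per taxon
    spike_shares_efficiency: bool = True   # mis-specification knob
    depth_yield_halfsat: float = 1e9       # molecules; ~yield of a 10-20 ml sample
    counted_volume: float = 0.025          # liters in the settling chamber
    detect_midpoint_um: float = 8.0        # ESD at half detectability
    detect_scale_um: float = 2.0
    detect_floor: float = 0.05
    blur_max: float = 0.8
    blur_midpoint_um: float = 10.0
    blur_scale_um: float = 2.0
    annotation_dropout: float = 0.1
    asv_split: bool = False                # split taxa into 1-5 ASVs
    dna_scale: float = 1e-8                # ng/ul per extracted molecule
    dna_noise_cv: float = 0.1
    station_salinity_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.copy_gamma < 0:
            raise ValueError("copy-number exponent gamma must be >= 0")
        if len(self.basin_names) != len(self.basin_salinities):
            raise ValueError("basin names and salinities differ in length")
        for name, value in (
            ("depth", self.depth), ("spike_molecules", self.spike_molecules),
            ("volume_filtered", self.volume_filtered),
            ("counted_volume", self.counted_volume),
            ("copy_kappa", self.copy_kappa),
            ("abundance_median", self.abundance_median),
        ):
            if value <= 0:
                raise ValueError(f"{name} must be > 0")
        for name, value in (
            ("annotation_dropout", self.annotation_dropout),
            ("blur_max", self.blur_max), ("detect_floor", self.detect_floor),
        ):
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth behind a simulated dataset.

    ``cells`` and ``molecules`` are samples x taxa; ``molecules`` equals
    ``cells`` scaled by the per-taxon copy number exactly.
    """

    taxa: pd.DataFrame       # lineage, volume, esd, copy_number, niche, group
    samples: pd.DataFrame    # station, basin, salinity, volume_filtered
    cells: pd.DataFrame      # true cells/L
    molecules: pd.DataFrame  # true marker molecules/L

    def with_samples(self, samples: pd.DataFrame, cells: pd.DataFrame) -> "SimulationTruth":
        kt = self.taxa["copy_number"]
        return SimulationTruth(self.taxa, samples, cells, cells * kt)


def _esd(volume_um3):
    """Equivalent spherical diameter (um) of a cell volume."""
    return (6.0 * np.asarray(volume_um3) / math.pi) ** (1.0 / 3.0)


def _mean_one_lognormal(rng, sigma, size):
    """Lognormal noise with unit mean."""
    if sigma <= 0:
        return np.ones(size)
    return rng.lognormal(-0.5 * sigma ** 2, sigma, size)


def _cv_to_sigma(cv: float) -> float:
    return math.sqrt(math.log(1.0 + cv ** 2)) if cv > 0 else 0.0


def simulate_truth(config: SimulationConfig, seed: int) -> SimulationTruth:
    """Draw taxa, stations and true cell concentrations.

    Cell concentration of taxon t in sample s is
    ``lambda_t * exp(-(s_s - mu_t)^2 / (2 sigma_t^2))`` times unit-mean
    lognormal noise, with station salinities around their basin means.
    """
    rng = np.random.default_rng(seed)

    taxa_rows = []
    for cls in config.classes:
        sg, dv, sd = CLASS_LINEAGES.get(cls, ("Eukaryota_X", "Unknown", "Unknown"))
        median_v = CLASS_MEDIAN_VOLUMES.get(cls, 200.0)
        for i in range(config.taxa_per_class):
            genus = f"{cls.replace('+', '')[:6]}_gen{i + 1}"
            species = f"{genus}_sp"
            v = float(rng.lognormal(math.log(median_v), config.volume_sigma_log))
            k = max(1, int(round(config.copy_kappa * v ** config.copy_gamma)))
            mu = float(rng.uniform(config.niche_min, config.niche_max))
            sig = float(max(1.5, rng.normal(config.niche_width_mean, config.niche_width_sd)))
            lam = float(rng.lognormal(math.log(config.abundance_median),
                                      config.abundance_sigma_log))
            taxa_rows.append({
                "taxon_id": f"T{len(taxa_rows) + 1:04d}",
                "supergroup": sg, "division": dv, "subdivision": sd,
                "class": cls, "order": f"{cls[:6]}ales",
                "family": f"{genus}aceae", "genus": genus, "species": species,
                "volume_um3": v, "esd_um": float(_esd(v)), "copy_number": k,
                "niche_mu": mu, "niche_sigma": sig, "lambda_base": lam,
                "group": group_for_class(cls),
            })
    taxa = pd.DataFrame(taxa_rows).set_index("taxon_id")

    sample_rows = []
    for b, (basin, sal) in enumerate(zip(config.basin_names, config.basin_salinities)):
        for st in range(config.stations_per_basin):
            station = f"ST{b + 1}{chr(65 + st)}"
            station_sal = max(0.5, sal + rng.normal(0.0, config.station_salinity_sd))
            for r in range(config.samples_per_station):
                sample_rows.append({
                    "sample_id": f"{station}_{r + 1:02d}",
                    "station": station, "basin": basin,
                    "date": f"2019-{(r % 12) + 1:02d}-15",
                    "salinity": station_sal,
                    "volume_filtered": config.volume_filtered,
                })
    samples = pd.DataFrame(sample_rows).set_index("sample_id")

    sal = samples["salinity"].to_numpy()[:, None]
    mu = taxa["niche_mu"].to_numpy()[None, :]
    sig = taxa["niche_sigma"].to_numpy()[None, :]
    lam = taxa["lambda_base"].to_numpy()[None, :]
    niche = np.exp(-((sal - mu) ** 2) / (2.0 * sig ** 2))
    noise = _mean_one_lognormal(rng, _cv_to_sigma(config.abundance_noise_cv),
                                (len(samples), len(taxa)))
    cells = pd.DataFrame(lam * niche * noise, index=samples.index, columns=taxa.index)
    molecules = cells * taxa["copy_number"]
    return SimulationTruth(taxa, samples, cells, molecules)


def _truncate_row(row: dict, rank: str | None) -> dict:
    """Clear lineage fields below ``rank`` (None clears everything)."""
    keep = -1 if rank is None else RANKS.index(rank)
    for i, r in enumerate(RANKS):
        if i > keep:
            row[r] = UNASSIGNED
    return row


def simulate_metabarcoding(truth: SimulationTruth, config: SimulationConfig,
                           seed: int) -> tuple[AsvTable, pd.DataFrame, pd.DataFrame]:
    """Observe the truth through filtration, extraction, PCR and sequencing.

    Returns (AsvTable, sample metadata, ASV taxonomy). The spike-in
    shares the sample's extraction efficiency (it is added before
    lysis), so the spike read ratio cancels it; setting
    ``spike_shares_efficiency=False`` breaks that assumption on purpose.
    """
    if config.depth <= 0:
        raise ValueError("sequencing depth must be > 0")
    rng = np.random.default_rng(seed)
    taxa, samples = truth.taxa, truth.samples
    n_s, n_t = len(samples), len(taxa)
    volumes = samples["volume_filtered"].to_numpy()

    captured = rng.poisson(truth.cells.to_numpy() * volumes[:, None])
    molecules_captured = captured * taxa["copy_number"].to_numpy()[None, :]
    eta = rng.lognormal(0.0, config.extraction_sigma, n_s)
    beta = rng.lognormal(0.0, config.pcr_bias_sigma, n_t) if config.pcr_bias_sigma > 0 else np.ones(n_t)

    spike_ids = [f"SPIKE{i + 1}" for i in range(config.n_spike_asvs)]
    eta_spike = eta if config.spike_shares_efficiency else rng.lognormal(0.0, config.extraction_sigma, n_s)
    spike_weight = (config.spike_molecules / config.n_spike_asvs) * eta_spike

    community_weight = molecules_captured * eta[:, None] * beta[None, :]
    weights = np.concatenate(
        [community_weight, np.repeat(spike_weight[:, None], config.n_spike_asvs, axis=1)],
        axis=1,
    )
    extracted = molecules_captured.sum(axis=1) * eta
    depth_s = np.round(
        config.depth * extracted / (extracted + config.depth_yield_halfsat)
    ).astype(int)

    reads = np.zeros_like(weights, dtype=np.int64)
    for s in range(n_s):
        total = weights[s].sum()
        if total > 0 and depth_s[s] > 0:
            reads[s] = rng.multinomial(depth_s[s], weights[s] / total)

    taxon_ids = list(taxa.index)
    if config.asv_split:
        split_counts = rng.integers(1, 6, n_t)
        asv_ids, tax_of_asv, columns = [], [], []
        for j, t in enumerate(taxon_ids):
            w = rng.dirichlet(np.ones(split_counts[j]))
            sub = np.zeros((n_s, split_counts[j]), dtype=np.int64)
            for s in range(n_s):
                if reads[s, j] > 0:
                    sub[s] = rng.multinomial(reads[s, j], w)
            for a in range(split_counts[j]):
                asv_ids.append(f"ASV_{t}_{a + 1}")
                tax_of_asv.append(t)
                columns.append(sub[:, a])
        community_reads = np.column_stack(columns)
    else:
        asv_ids = [f"ASV_{t}" for t in taxon_ids]
        tax_of_asv = taxon_ids
        community_reads = reads[:, :n_t]

    counts = pd.DataFrame(
        np.concatenate([community_reads, reads[:, n_t:]], axis=1),
        index=samples.index, columns=asv_ids + spike_ids, dtype=np.int64,
    )
    asv = AsvTable(counts, tuple(spike_ids))

    # ASV taxonomy with annotation dropout (reference-database gaps)
    tax_rows = []
    for asv_id, t in zip(asv_ids, tax_of_asv):
        row = {r: taxa.loc[t, r] for r in RANKS}
        if rng.random() < config.annotation_dropout:
            level = rng.choice(["genus", "order", None])
            row = _truncate_row(row, level)
        row["asv_id"] = asv_id
        tax_rows.append(row)
    for spike in spike_ids:
        tax_rows.append({**{r: UNASSIGNED for r in RANKS}, "asv_id": spike})
    taxonomy = pd.DataFrame(tax_rows).set_index("asv_id")[list(RANKS)]

    dna_noise = _mean_one_lognormal(rng, _cv_to_sigma(config.dna_noise_cv), n_s)
    metadata = samples.copy()
    metadata["dna_concentration"] = config.dna_scale * extracted * dna_noise
    metadata["spike_molecules"] = config.spike_molecules
    metadata["total_reads"] = depth_s
    return asv, metadata, taxonomy


def simulate_microscopy(truth: SimulationTruth, config: SimulationConfig,
                        seed: int, carbon_model: CarbonModel | None = None) -> pd.DataFrame:
    """Observe the truth through the settling chamber.

    Counts are Poisson in the counted volume with logistic size-dependent
    detectability; with size-dependent blur probability a record's
    lineage is truncated to order or class. Biovolume and carbon derive
    from the carbon model.
    """
    rng = np.random.default_rng(seed)
    model = carbon_model or CarbonModel()
    taxa, samples = truth.taxa, truth.samples
    esd = taxa["esd_um"].to_numpy()
    detect = config.detect_floor + (1.0 - config.detect_floor) * expit(
        (esd - config.detect_midpoint_um) / config.detect_scale_um)
    blur = config.blur_max * expit(
        (config.blur_midpoint_um - esd) / config.blur_scale_um)

    lam = truth.cells.to_numpy() * config.counted_volume * detect[None, :]
    counts = rng.poisson(lam)
    rows = []
    for s, sample_id in enumerate(samples.index):
        for j, t in enumerate(taxa.index):
            if counts[s, j] == 0:
                continue
            cells_rep = counts[s, j] / config.counted_volume
            v = taxa.loc[t, "volume_um3"]
            c_pg = carbon_per_cell(v, taxa.loc[t, "group"], model)
            row = {r: taxa.loc[t, r] for r in RANKS}
            if rng.random() < blur[j]:
                row = _truncate_row(row, rng.choice(["order", "class"]))
            row.update({
                "sample_id": sample_id,
                "cells_per_liter": cells_rep,
                "biovolume_um3_per_liter": cells_rep * v,
                "carbon_ugC_per_liter": cells_rep * c_pg * 1e-6,
            })
            rows.append(row)
    columns = ["sample_id", *RANKS, "cells_per_liter",
               "biovolume_um3_per_liter", "carbon_ugC_per_liter"]
    return pd.DataFrame(rows, columns=columns)


@dataclass(frozen=True)
class ReplicateStudy:
    """Paired replicate tests plus a filtered-volume series."""

    occasions: tuple[dict, ...]
    volume_series: dict


def _expand_occasion(truth: SimulationTruth, cells_row: np.ndarray,
                     base: pd.Series, n_replicates: int,
                     volumes: np.ndarray, prefix: str) -> SimulationTruth:
    """Replicate one true community into n observation-ready samples."""
    rows, cell_rows = [], []
    for i in range(n_replicates):
        rows.append({
            "sample_id": f"{prefix}_R{i + 1}",
            "station": base["station"], "basin": base["basin"],
            "date": base["date"], "salinity": base["salinity"],
            "volume_filtered": float(volumes[i]),
            "replicate_id": i + 1,
        })
        cell_rows.append(cells_row)
    samples = pd.DataFrame(rows).set_index("sample_id")
    cells = pd.DataFrame(np.vstack(cell_rows), index=samples.index,
                         columns=truth.taxa.index)
    return truth.with_samples(samples, cells)


def simulate_replicate_study(config: SimulationConfig, seed: int,
                             n_occasions: int = 6, n_replicates: int = 5) -> ReplicateStudy:
    """Replication tests (default six occasions x five replicates per
    method) and a filtered-volume series (each volume x five replicates).

    Replicates of an occasion share one true community; between-replicate
    variance stems only from the observation layers (filtration capture
    and sequencing for MB, chamber counting for UM).
    """
    rng = np.random.default_rng(seed)
    base_truth = simulate_truth(config, int(rng.integers(2 ** 31)))
    # occasions alternate between a marine and a brackish station
    occ_salinities = [28.5 if i % 2 == 0 else 5.0 for i in range(n_occasions)]

    occasions = []
    for i, sal in enumerate(occ_salinities):
        occ_seed = int(rng.integers(2 ** 31))
        occ_rng = np.random.default_rng(occ_seed)
        taxa = base_truth.taxa
        niche = np.exp(-((sal - taxa["niche_mu"].to_numpy()) ** 2)
                       / (2.0 * taxa["niche_sigma"].to_numpy() ** 2))
        noise = _mean_one_lognormal(occ_rng, _cv_to_sigma(config.abundance_noise_cv),
                                    len(taxa))
        cells_row = taxa["lambda_base"].to_numpy() * niche * noise
        base = pd.Series({"station": "OCC", "basin": "replication",
                          "date": f"2019-{i + 1:02d}-01", "salinity": sal})
        occ_truth = _expand_occasion(
            base_truth, cells_row, base, n_replicates,
            np.full(n_replicates, config.volume_filtered), f"OCC{i + 1}")
        asv, meta, taxonomy = simulate_metabarcoding(
            occ_truth, config, int(occ_rng.integers(2 ** 31)))
        micro = simulate_microscopy(occ_truth, config, int(occ_rng.integers(2 ** 31)))
        occasions.append({
            "occasion_id": f"OCC{i + 1}", "salinity": sal, "truth": occ_truth,
            "asv": asv, "metadata": meta, "taxonomy": taxonomy,
            "microscopy": micro,
        })

    # volume series at one marine occasion
    vol_rng = np.random.default_rng(int(rng.integers(2 ** 31)))
    taxa = base_truth.taxa
    sal = occ_salinities[0]
    niche = np.exp(-((sal - taxa["niche_mu"].to_numpy()) ** 2)
                   / (2.0 * taxa["niche_sigma"].to_numpy() ** 2))
    noise = _mean_one_lognormal(vol_rng, _cv_to_sigma(config.abundance_noise_cv), len(taxa))
    cells_row = taxa["lambda_base"].to_numpy() * niche * noise
    volumes = np.repeat(config.volume_options, n_replicates)
    base = pd.Series({"station": "VOL", "basin": "volume-test",
                      "date": "2019-05-06", "salinity": sal})
    vol_truth = _expand_occasion(base_truth, cells_row, base,
                                 len(volumes), volumes, "VOL")
    asv, meta, taxonomy = simulate_metabarcoding(
        vol_truth, config, int(vol_rng.integers(2 ** 31)))
    volume_series = {"truth": vol_truth, "asv": asv, "metadata": meta,
                     "taxonomy": taxonomy}
    return ReplicateStudy(tuple(occasions), volume_series)


def simulate_volume_scenario(config: SimulationConfig, seed: int,
                             c_min: float = 50.0, c_max: float = 1.5e4,
                             n_replicates: int = 5,
                             depth_yield_halfsat: float = 5e7) -> tuple[AsvTable, pd.DataFrame]:
    """Filtered-volume validation series on a bounded community.

    Emulates a dedicated technical validation of filtered volume: one
    water batch, each volume option filtered in replicate. The true
    community is a log-spaced concentration ladder bounded below at
    ``c_min`` so that every taxon is comfortably captured from 200 ml
    up (>= ~5 cells on the filter and >= ~5 expected reads) while a
    sizable share of taxa sits below the 10 ml capture threshold of
    ~100 cells/L. The library-input half-saturation is lowered so that
    sequencing depth is input-limited only below ~100 ml, as when
    libraries are pooled equimolar. Returns the ASV table and metadata
    of the volume series.
    """
    rng = np.random.default_rng(seed)
    base_truth = simulate_truth(config, int(rng.integers(2 ** 31)))
    n_t = len(base_truth.taxa)
    ladder = np.logspace(math.log10(c_min), math.log10(c_max), n_t)
    ladder = ladder * rng.lognormal(0.0, 0.2, n_t)
    rng.shuffle(ladder)
    base = pd.Series({"station": "VOL", "basin": "volume-test",
                      "date": "2019-05-06", "salinity": 28.5})
    volumes = np.repeat(config.volume_options, n_replicates)
    vol_truth = _expand_occasion(base_truth, ladder, base, len(volumes),
                                 volumes, "VOL")
    obs_config = replace(config, depth_yield_halfsat=depth_yield_halfsat)
    asv, metadata, _ = simulate_metabarcoding(vol_truth, obs_config,
                                              int(rng.integers(2 ** 31)))
    return asv, metadata


def richness_totals(asv: AsvTable, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-sample totals for the volume-saturation analysis."""
    nonspike = asv.nonspike_counts()
    return pd.DataFrame({
        "total_reads": metadata.loc[asv.sample_ids, "total_reads"],
        "phyto_reads": nonspike.sum(axis=1),
        "phyto_richness": (nonspike > 0).sum(axis=1),
    })


def simulate_dataset(config: SimulationConfig, seed: int):
    """Convenience: truth + metabarcoding + microscopy in one call."""
    rng = np.random.default_rng(seed)
    truth = simulate_truth(config, int(rng.integers(2 ** 31)))
    asv, metadata, taxonomy = simulate_metabarcoding(truth, config, int(rng.integers(2 ** 31)))
    microscopy = simulate_microscopy(truth, config, int(rng.integers(2 ** 31)))
    return truth, asv, metadata, taxonomy, microscopy


def evaluate_spike_recovery(truth: SimulationTruth, asv: AsvTable,
                            metadata: pd.DataFrame,
                            min_true_proportion: float = 1e-3) -> dict:
    """Compare spike-normalized estimates against true molecules/L.

    The error median and the log-log regression are computed over
    taxon x sample pairs inside the quantification range: pairs whose
    true within-sample molecule proportion is at least
    ``min_true_proportion`` (below it detection, not quantification, is
    limiting). ASV columns must map 1:1 onto taxa (``asv_split`` off).
    """
    from .compare import fit_loglog

    est = spike_normalize(asv, metadata)
    true = truth.molecules.loc[est.data.index]
    true.columns = [f"ASV_{t}" for t in true.columns]
    true = true[est.data.columns]
    prop = true.div(true.sum(axis=1), axis=0)
    mask = (prop >= min_true_proportion).to_numpy()
    t = true.to_numpy()[mask]
    e = est.data.to_numpy()[mask]
    rel_err = np.abs(e - t) / t
    res = fit_loglog(t, e, zero_policy="drop")
    return {
        "slope": res.slope, "r2": res.r2,
        "median_relative_error": float(np.median(rel_err)),
        "n_pairs": int(mask.sum()), "n_excluded_zero": res.n_excluded,
    }
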