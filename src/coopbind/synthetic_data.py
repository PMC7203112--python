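"""Synthetic inputs with the statistical structure the analysis assumes.

Four generators, each a pure function of (specification, seed):

* genomes with planted motif arrangements of known per-class affinity,
* single-end reads whose local density follows background-plus-occupancy
  enrichment around planted sites,
* MST-style titrations from the 1:1 depletion isotherm with multiplicative
  noise, and
* ITC injection series from the sequential two-event model with additive
  noise.

Per-class affinity feeds read enrichment through an effective single-Kd
occupancy θ = P/(P + Kd): the downstream ECDF analysis only consumes the
rank ordering of enrichment, so the full two-site binding polynomial is not
needed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .binding_models import (
    ITCExperiment,
    SequentialBindingParams,
    TitrationSeries,
    predict_itc_heats,
    predict_mst_signal,
)
from .motif_grammar import ArrangementSpec, expand_arrangement

__all__ = [
    "PlantSpec",
    "SyntheticGenomeSpec",
    "ReadSimSpec",
    "GenerationError",
    "generate_genome",
    "site_occupancy",
    "simulate_reads",
    "simulate_mst_titration",
    "simulate_itc_experiment",
    "DEFAULT_ITC_GEOMETRY",
    "DEFAULT_MST_TITRANT_UM",
]

# study design defaults: 16 log-spaced DNA points 0.001-100 µM, 50 nM label
DEFAULT_MST_TITRANT_UM = np.logspace(-3, 2, 16)
DEFAULT_MST_LABELED_UM = 0.05

# 19 x 2 µL injections into a 200 µL cell; 30 µM DNA, 450 µM protein
DEFAULT_ITC_GEOMETRY = dict(
    cell_volume=200.0, cell_DNA=30.0, syringe_protein=450.0,
    injection_volumes=tuple([2.0] * 19),
)


class GenerationError(RuntimeError):
    """Raised when a synthetic artifact cannot satisfy its specification."""


@dataclass(frozen=True)
class PlantSpec:
    """One motif class to plant: arrangement, copy count, class affinity."""

    arrangement: ArrangementSpec
    count: int
    kd: float  # µM, effective class affinity

    def __post_init__(self):
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if self.kd <= 0:
            raise ValueError("kd must be > 0")


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    n_chroms: int = 1
    chrom_length: int = 50_000
    gc_fraction: float = 0.36  # A. thaliana-like background
    plants: tuple[PlantSpec, ...] = ()
    min_plant_spacing: int = 150
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "plants", tuple(self.plants))
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError("gc_fraction must be in [0, 1]")
        if self.n_chroms < 1 or self.chrom_length < 1:
            raise ValueError("need at least one chromosome of positive length")
        footprint = sum(p.count * p.arrangement.composite_length for p in self.plants)
        if footprint >= self.n_chroms * self.chrom_length:
            raise ValueError("total planted footprint exceeds genome length")


@dataclass(frozen=True)
class ReadSimSpec:
    background_rate: float = 2.0  # reads per kb, uniform
    enrichment_scale: float = 80.0  # expected extra reads at full occupancy
    nuclear_protein: float = 1.0  # µM, effective free protein in nuclei
    read_length: int = 50
    positional_jitter_sd: float = 30.0  # nt, spread of site-driven reads
    seed: int = 0

    def __post_init__(self):
        if min(self.background_rate, self.enrichment_scale, self.positional_jitter_sd) < 0:
            raise ValueError("rates must be >= 0")
        if self.nuclear_protein <= 0:
            raise ValueError("nuclear_protein must be > 0")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")


def _background_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=p)


def generate_genome(spec: SyntheticGenomeSpec) -> tuple[dict[str, str], pd.DataFrame]:
    """Background genome with planted composite elements and a truth table.

    Background bases are i.i.d. at the requested GC content; each planted
    site is the concrete composite of its arrangement, placed uniformly at
    random without overlap and respecting ``min_plant_spacing``. Returns
    ``(sequences, truth)`` where truth has columns chrom, start, end,
    class_label, kd, strand. Deterministic for a given spec (seed included).
    """
    ss = np.random.SeedSequence(spec.seed)
    chrom_ss, place_ss = ss.spawn(2)
    chrom_rngs = [np.random.default_rng(s) for s in chrom_ss.spawn(spec.n_chroms)]
    place_rng = np.random.default_rng(place_ss)

    chroms = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    seqs = {
        c: _background_bases(rng, spec.chrom_length, spec.gc_fraction)
        for c, rng in zip(chroms, chrom_rngs)
    }

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    rows = []
    for plant in spec.plants:
        probe = expand_arrangement(plant.arrangement)
        width = len(probe)
        for _ in range(plant.count):
            placed = False
            for _attempt in range(1000):
                chrom = chroms[int(place_rng.integers(spec.n_chroms))]
                if spec.chrom_length - width <= 0:
                    break
                start = int(place_rng.integers(spec.chrom_length - width + 1))
                end = start + width
                gap = spec.min_plant_spacing
                if all(start - gap >= e or end + gap <= s for s, e in occupied[chrom]):
                    occupied[chrom].append((start, end))
                    seqs[chrom][start:end] = np.frombuffer(probe.encode(), dtype="S1")
                    rows.append((chrom, start, end, plant.arrangement.name, plant.kd, "+"))
                    placed = True
                    break
            if not placed:
                raise GenerationError(
                    f"could not place plant of class {plant.arrangement.name!r} "
                    f"after bounded retries"
                )
    truth = pd.DataFrame(rows, columns=["chrom", "start", "end", "class_label", "kd", "strand"])
    truth = truth.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    sequences = {c: s.tobytes().decode() for c, s in seqs.items()}
    return sequences, truth


def site_occupancy(kd: float, nuclear_protein: float) -> float:
    """Effective fractional occupancy θ = P/(P + Kd) of a site class."""
    if kd <= 0 or nuclear_protein <= 0:
        raise ValueError("kd and nuclear_protein must be > 0")
    return nuclear_protein / (nuclear_protein + kd)


def simulate_reads(
    chrom_sizes: dict[str, int],
    truth: pd.DataFrame,
    spec: ReadSimSpec,
) -> pd.DataFrame:
    """Single-end reads: uniform Poisson background plus site enrichment.

    Background reads per chromosome are Poisson(background_rate·length/1000)
    with uniform start positions. Each planted site contributes
    Poisson(enrichment_scale·θ) extra reads centered on the site with
    Gaussian positional jitter; reads are clipped to chromosome bounds.
    Returns a BED-like DataFrame (chrom, start, end, name, score, strand).
    """
    ss = np.random.SeedSequence(spec.seed)
    bg_ss, site_ss = ss.spawn(2)
    rows = []
    L = spec.read_length
    bg_rngs = bg_ss.spawn(len(chrom_sizes))
    for (chrom, size), child in zip(sorted(chrom_sizes.items()), bg_rngs):
        rng = np.random.default_rng(child)
        n = rng.poisson(spec.background_rate * size / 1000.0)
        if size <= L:
            starts = np.zeros(n, dtype=int)
        else:
            starts = rng.integers(0, size - L + 1, size=n)
        for s in np.sort(starts):
            rows.append((chrom, int(s), int(min(s + L, size)), "bg", 0, "+"))
    site_rngs = site_ss.spawn(len(truth))
    for (_, site), child in zip(truth.iterrows(), site_rngs):
        rng = np.random.default_rng(child)
        size = chrom_sizes[site["chrom"]]
        theta = site_occupancy(float(site["kd"]), spec.nuclear_protein)
        n = rng.poisson(spec.enrichment_scale * theta)
        center = (site["start"] + site["end"]) / 2.0
        centers = center + rng.normal(0.0, spec.positional_jitter_sd, size=n)
        starts = np.clip(np.round(centers).astype(int) - L // 2, 0, max(size - L, 0))
        for s in np.sort(starts):
            rows.append((site["chrom"], int(s), int(min(s + L, size)), "site", 0, "+"))
    reads = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    return reads.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def simulate_mst_titration(
    kd: float,
    labeled_total: float = DEFAULT_MST_LABELED_UM,
    titrant_total: Sequence[float] | np.ndarray = DEFAULT_MST_TITRANT_UM,
    n_replicates: int = 3,
    noise_cv: float = 0.03,
    baseline: float = 0.0,
    amplitude: float = 1.0,
    seed: int = 0,
) -> list[TitrationSeries]:
    """Replicate titration series with multiplicative Gaussian noise.

    signal = (baseline + amplitude·f_bound) · (1 + ε), ε ~ N(0, noise_cv),
    drawn independently per point and replicate.
    """
    titrant = np.asarray(titrant_total, dtype=float)
    if titrant.size == 0:
        raise ValueError("titrant grid must be non-empty")
    rngs = np.random.SeedSequence(seed).spawn(n_replicates)
    clean = predict_mst_signal(labeled_total, titrant, kd, baseline, amplitude)
    series = []
    for i, child in enumerate(rngs):
        rng = np.random.default_rng(child)
        eps = rng.normal(0.0, noise_cv, size=titrant.size) if noise_cv > 0 else 0.0
        series.append(
            TitrationSeries(labeled_total, titrant, clean * (1.0 + eps), replicate_id=f"rep{i + 1}")
        )
    return series


def simulate_itc_experiment(
    params: SequentialBindingParams,
    cell_volume: float = DEFAULT_ITC_GEOMETRY["cell_volume"],
    cell_DNA: float = DEFAULT_ITC_GEOMETRY["cell_DNA"],
    syringe_protein: float = DEFAULT_ITC_GEOMETRY["syringe_protein"],
    injection_volumes: Sequence[float] = DEFAULT_ITC_GEOMETRY["injection_volumes"],
    noise_sd: float = 0.0,
    dilution_offset: float = 0.0,
    seed: int = 0,
) -> ITCExperiment:
    """Two-event ITC injection series with additive Gaussian heat noise."""
    exp = ITCExperiment(
        cell_volume=cell_volume,
        cell_DNA=cell_DNA,
        syringe_protein=syringe_protein,
        injection_volumes=np.asarray(injection_volumes, dtype=float),
        heats=np.zeros(len(injection_volumes)),
    )
    heats = predict_itc_heats(exp, params, dilution_offset)
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        heats = heats + rng.normal(0.0, noise_sd, size=heats.size)
    exp.heats = heats
    return exp
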