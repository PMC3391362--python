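"""Species-level karyotype records and the limiting-component centromere model.

The central biological idea is that a cell allocates a total centromere
"budget" — a fixed amount of CENH3 chromatin that scales with genome size —
and partitions it across however many chromosomes the genome happens to be
divided into.  A genome split into few chromosomes has large individual
centromeres; the same genome split into many chromosomes has small ones, with
the total unchanged.  This module holds the species records, the derived
average-chromosome-size quantity, the budget partitioner, and a simulator
that produces species panels with a known linear area-vs-genome-size law for
exercising the statistics layer.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesRecord",
    "SpeciesPanel",
    "average_chromosome_size",
    "round_half_away",
    "partition_centromere_budget",
    "simulate_species_panel",
    "load_table1",
    "read_panel_csv",
    "write_panel_csv",
]

#: Column order for species-table CSV files; empty cells mean missing.
PANEL_CSV_COLUMNS = [
    "name",
    "genome_size_mb",
    "chromosome_number",
    "total_centromere_area",
    "microtubules_per_kinetochore",
]

#: Haploid chromosome numbers of the ten grass study species span 7-21.
DEFAULT_CHROMOSOME_NUMBER_RANGE = (7, 21)

#: Grass haploid genome sizes span >30-fold; 400 Mb (rice) to 16,000 Mb
#: (hexaploid wheat) covers the realistic range, sampled log-uniformly.
DEFAULT_GENOME_SIZE_RANGE = (400.0, 16000.0)


def round_half_away(value: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (the convention of printed
    karyotype tables), unlike Python's default banker's rounding.

    >>> round_half_away(41.25)
    41.3
    """
    factor = 10.0**ndigits
    scaled = value * factor
    return math.floor(abs(scaled) + 0.5) / factor * (1 if scaled >= 0 else -1)


def average_chromosome_size(
    genome_size: float, chromosome_number: int, rounded: bool = False
) -> float:
    """Average chromosome size in Mb: haploid genome size divided by haploid
    chromosome number.

    Parameters
    ----------
    genome_size : float
        Haploid genome size in megabases; must be positive.
    chromosome_number : int
        Haploid chromosome number; must be >= 1.
    rounded : bool
        When True, round to one decimal (half away from zero) as in printed
        karyotype tables.  Raw values are used everywhere internally.
    """
    if not genome_size > 0:
        raise ValueError(f"genome_size must be positive, got {genome_size}")
    if chromosome_number < 1:
        raise ValueError(
            f"chromosome_number must be >= 1, got {chromosome_number}"
        )
    value = genome_size / chromosome_number
    return round_half_away(value, 1) if rounded else value


@dataclass(frozen=True)
class SpeciesRecord:
    """One species' karyotype and measured traits.

    ``total_centromere_area`` is the summed CENH3 staining area over all
    centromeres of a cell (arbitrary projected-pixel units, comparable only
    within a study); ``microtubules_per_kinetochore`` is the mean spindle
    microtubule count per kinetochore.  Both are optional because different
    analyses use different subsets of traits.
    """

    name: str
    genome_size_mb: float
    chromosome_number: int
    total_centromere_area: float | None = None
    microtubules_per_kinetochore: float | None = None

    def __post_init__(self) -> None:
        if not self.genome_size_mb > 0:
            raise ValueError(
                f"{self.name}: genome_size_mb must be positive, "
                f"got {self.genome_size_mb}"
            )
        if self.chromosome_number < 1:
            raise ValueError(
                f"{self.name}: chromosome_number must be >= 1, "
                f"got {self.chromosome_number}"
            )

    @property
    def average_chromosome_size(self) -> float:
        """Derived, never stored: genome size / chromosome number (Mb)."""
        return average_chromosome_size(self.genome_size_mb, self.chromosome_number)

    def average_chromosome_size_display(self) -> float:
        """Average chromosome size rounded to one decimal for table display."""
        return average_chromosome_size(
            self.genome_size_mb, self.chromosome_number, rounded=True
        )

    def with_area(self, total_centromere_area: float) -> "SpeciesRecord":
        return replace(self, total_centromere_area=total_centromere_area)


@dataclass
class SpeciesPanel:
    """An ordered collection of species records with a provenance tag."""

    records: list[SpeciesRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        names = [r.name for r in self.records]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate species names: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, name: str) -> SpeciesRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "name": r.name,
                "genome_size_mb": r.genome_size_mb,
                "chromosome_number": r.chromosome_number,
                "total_centromere_area": r.total_centromere_area,
                "microtubules_per_kinetochore": r.microtubules_per_kinetochore,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=PANEL_CSV_COLUMNS)


def partition_centromere_budget(
    total_area: float,
    chromosome_number: int,
    dispersion: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Split a total centromere area budget across chromosomes.

    The limiting-component idealization is an exactly equal partition: the
    same total is conserved whether the genome is packaged into few large or
    many small centromeres.  ``dispersion`` (area units, standard deviation)
    adds mean-preserving per-centromere noise so the sum stays exactly
    ``total_area``.
    """
    if total_area < 0:
        raise ValueError(f"total_area must be non-negative, got {total_area}")
    if chromosome_number < 1:
        raise ValueError(
            f"chromosome_number must be >= 1, got {chromosome_number}"
        )
    shares = np.full(chromosome_number, total_area / chromosome_number)
    if dispersion > 0:
        rng = np.random.default_rng() if rng is None else rng
        noise = rng.normal(0.0, dispersion, chromosome_number)
        shares = shares + (noise - noise.mean())
    return shares


def simulate_species_panel(
    n_species: int = 10,
    slope: float = 0.1,
    intercept: float = 100.0,
    noise_sd: float = 50.0,
    genome_size_range: tuple[float, float] = DEFAULT_GENOME_SIZE_RANGE,
    chromosome_number_range: tuple[int, int] = DEFAULT_CHROMOSOME_NUMBER_RANGE,
    seed: int = 0,
    names: Sequence[str] | None = None,
) -> SpeciesPanel:
    """Simulate a species panel whose total centromere area is linear in
    genome size.

    Genome sizes are drawn log-uniformly over ``genome_size_range`` (grass
    genome sizes span more than 30-fold, so a log-uniform draw reproduces the
    dynamic range); haploid chromosome numbers are uniform integers over
    ``chromosome_number_range``, independent of genome size; and

        total_centromere_area = intercept + slope * genome_size + N(0, noise_sd)

    in arbitrary area units.  The defaults give panels in the regime the
    statistics layer is meant for: a strong genome-size correlation
    (R^2 ~ 0.98) with chromosome number uninformative.  Reproducible for a
    fixed seed.

    Parameters
    ----------
    names : sequence of str, optional
        Species names; defaults to ``sp00 .. spNN``.  Supplying the grass
        tip names lets the panel feed the phylogenetic-contrasts layer.
    """
    if n_species < 3:
        raise ValueError(f"n_species must be >= 3, got {n_species}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    g_lo, g_hi = genome_size_range
    if not (0 < g_lo <= g_hi) or not np.isfinite([g_lo, g_hi, slope]).all():
        raise ValueError(f"invalid genome_size_range {genome_size_range}")
    c_lo, c_hi = chromosome_number_range
    if not (1 <= c_lo <= c_hi):
        raise ValueError(
            f"invalid chromosome_number_range {chromosome_number_range}"
        )
    if names is not None and len(names) != n_species:
        raise ValueError(
            f"got {len(names)} names for {n_species} species"
        )

    rng = np.random.default_rng(seed)
    genome_sizes = np.exp(
        rng.uniform(np.log(g_lo), np.log(g_hi), n_species)
    )
    chrom_numbers = rng.integers(c_lo, c_hi + 1, n_species)
    areas = intercept + slope * genome_sizes
    if noise_sd > 0:
        areas = areas + rng.normal(0.0, noise_sd, n_species)

    if names is None:
        names = [f"sp{i:02d}" for i in range(n_species)]
    records = [
        SpeciesRecord(
            name=str(names[i]),
            genome_size_mb=float(genome_sizes[i]),
            chromosome_number=int(chrom_numbers[i]),
            total_centromere_area=float(areas[i]),
        )
        for i in range(n_species)
    ]
    return SpeciesPanel(records=records, provenance=f"simulated seed={seed}")


# ---------------------------------------------------------------------------
# CSV I/O and the packaged microtubule table
# ---------------------------------------------------------------------------

def _record_from_row(row: pd.Series) -> SpeciesRecord:
    def opt(key: str) -> float | None:
        v = row.get(key)
        return None if v is None or pd.isna(v) else float(v)

    return SpeciesRecord(
        name=str(row["name"]),
        genome_size_mb=float(row["genome_size_mb"]),
        chromosome_number=int(row["chromosome_number"]),
        total_centromere_area=opt("total_centromere_area"),
        microtubules_per_kinetochore=opt("microtubules_per_kinetochore"),
    )


def read_panel_csv(path_or_buffer, provenance: str | None = None) -> SpeciesPanel:
    """Read a species table CSV (columns: name, genome_size_mb,
    chromosome_number, total_centromere_area, microtubules_per_kinetochore;
    empty cell = missing)."""
    df = pd.read_csv(path_or_buffer)
    missing = set(PANEL_CSV_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"species CSV missing columns: {sorted(missing)}")
    records = [_record_from_row(row) for _, row in df.iterrows()]
    return SpeciesPanel(
        records=records,
        provenance=provenance if provenance is not None else str(path_or_buffer),
    )


def write_panel_csv(panel: SpeciesPanel, path) -> None:
    panel.to_dataframe().to_csv(path, index=False)


def load_table1() -> SpeciesPanel:
    """The packaged ten-species kinetochore-microtubule table: published
    haploid genome sizes, chromosome numbers, and microtubule counts per
    kinetochore for species from yeasts to *Haemanthus*."""
    text = (
        resources.files("cenarea.data")
        .joinpath("table1_microtubules.csv")
        .read_text()
    )
    return read_panel_csv(io.StringIO(text), provenance="table1")
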