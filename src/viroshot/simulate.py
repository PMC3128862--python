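"""Synthetic inputs for the pipeline: genomes, clone reads, hit tables,
gradient profiles, and paired libraries with controlled genome overlap.

The generators emulate the structure of a direct-cloned marine virome
study: viral genomes drawn from four size classes (30-45 kb, 60-80 kb,
125 kb, >146 kb), sheared inserts size-selected to 1.4-4 kb with
forward/reverse end reads arrayed in 96-well plates, similarity-hit tables
with a configurable per-source composition and per-source E-value decade
ranges, and CsCl gradient profiles with virus-like particles peaking in
the low-density top fractions (buoyant density ~1.44-1.47 g/ml).

All generators are deterministic for a given seed: one global integer seed
expands to fixed per-stream sub-seeds (see :func:`viroshot._util.subseed`)
so each generator can be re-run independently.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import revcomp, subseed
from .annotation import HIT_COLUMNS, SOURCE_CATEGORIES
from .assembly import Read
from .accounting import GradientFraction
from .compare import LibraryProfile, naive_cross_search

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: The four genome size classes (min bp, max bp, weight). The study gives
#: no class abundances, so equal weights are assumed; the open class is
#: capped at 200 kb.
DEFAULT_SIZE_CLASSES = (
    (30_000, 45_000, 0.25),
    (60_000, 80_000, 0.25),
    (125_000, 125_000, 0.25),
    (146_000, 200_000, 0.25),
)

#: Source composition of top hits against a curated (nr-like) database:
#: ~8.2% viral split phage-heavy, 15.3% bacteria, 0.5% archaea, 1.1%
#: eukaryote, 0.6% mobile elements, remainder without a hit.
DEFAULT_COMPOSITION = {
    "bacteriophage": 0.0771,
    "eukaryotic_virus": 0.0049,
    "mobile_element": 0.006,
    "bacteria": 0.153,
    "archaea": 0.005,
    "eukaryote": 0.011,
    "none": 0.743,
}

DEFAULT_EVALUE_RANGES = {cat: (-20.0, -1.0) for cat in SOURCE_CATEGORIES}

_DESCRIPTIONS = {
    "bacteriophage": (
        "major capsid protein [Enterobacteria phage T4]",
        "terminase large subunit [Bacteriophage P22]",
        "portal protein [Synechococcus phage S-PM2]",
        "baseplate assembly protein [Vibrio phage KVP40]",
        "tail fiber protein [Pseudomonas phage phiKZ]",
        "prophage integrase [Escherichia coli K-12]",
    ),
    "eukaryotic_virus": (
        "DNA polymerase [Paramecium bursaria Chlorella virus 1]",
        "major capsid protein [Acanthamoeba polyphaga mimivirus]",
        "helicase [Emiliania huxleyi virus 86]",
    ),
    "viral_metagenome": (
        "uncultured marine virus clone, environmental virome",
        "uncultured phage clone from coastal virioplankton",
    ),
    "mobile_element": (
        "transposase, IS200/IS605 family",
        "conjugative transfer protein TraG",
    ),
    "bacteria": (
        "DNA gyrase subunit B [Shewanella sp.]",
        "hypothetical protein [Candidatus Pelagibacter ubique]",
        "30S ribosomal protein S12 [Vibrio splendidus]",
        "TonB-dependent receptor [Polaribacter sp.]",
    ),
    "archaea": (
        "ammonia monooxygenase subunit A [Nitrosopumilus maritimus]",
        "hypothetical protein [Cenarchaeum symbiosum]",
    ),
    "eukaryote": (
        "actin [Thalassiosira pseudonana]",
        "tubulin beta chain [Emiliania huxleyi]",
    ),
    "microbial_metagenome": (
        "unidentified ORF, marine microbial metagenome clone",
        "predicted protein, ocean surface water sample",
    ),
    "unknown": ("hypothetical protein, unclassified environmental sequence",),
}

_WELL_ROWS = "ABCDEFGH"
_WELL_COLS = 12


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeModel:
    size_classes: tuple[tuple[int, int, float], ...] = DEFAULT_SIZE_CLASSES
    n_genomes: int = 40
    gc_fraction: float = 0.45

    def __post_init__(self) -> None:
        weights = [w for _, _, w in self.size_classes]
        if not self.size_classes or not math.isclose(sum(weights), 1.0,
                                                     abs_tol=1e-9):
            raise ValueError("size-class weights must sum to 1")
        if any(w < 0 for w in weights):
            raise ValueError("size-class weights must be non-negative")
        if any(lo > hi or lo < 1 for lo, hi, _ in self.size_classes):
            raise ValueError("size classes need 1 <= min_bp <= max_bp")
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        if not 0 <= self.gc_fraction <= 1:
            raise ValueError("gc_fraction must be in [0, 1]")


@dataclass(frozen=True)
class CloneModel:
    insert_min_bp: int = 1400
    insert_max_bp: int = 4000
    read_len_mean: float = 600.0
    read_len_sd: float = 120.0
    paired_fraction: float = 1.0
    duplicate_clone_rate: float = 0.0
    read_len_floor: int = 100

    def __post_init__(self) -> None:
        if self.insert_min_bp < self.read_len_floor:
            raise ValueError("insert_min_bp must be >= read length floor")
        if self.insert_min_bp > self.insert_max_bp:
            raise ValueError("insert_min_bp must be <= insert_max_bp")
        for p in (self.paired_fraction, self.duplicate_clone_rate):
            if not 0 <= p <= 1:
                raise ValueError("proportions must be in [0, 1]")
        if self.read_len_mean <= 0 or self.read_len_sd < 0:
            raise ValueError("read length parameters must be positive")


@dataclass(frozen=True)
class HitModel:
    """Composition may include a ``none`` key: the proportion of queries
    that receive no hit at all (applied after ``hit_rate``)."""

    composition: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION)
    )
    evalue_log10_range: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EVALUE_RANGES)
    )
    hit_rate: float = 1.0
    hits_per_query_mean: float = 1.0

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.composition.values()), 1.0, abs_tol=1e-9):
            raise ValueError("composition proportions must sum to 1")
        bad = set(self.composition) - set(SOURCE_CATEGORIES) - {"none"}
        if bad:
            raise ValueError(f"unknown composition categories: {sorted(bad)}")
        for cat, (lo, hi) in self.evalue_log10_range.items():
            if lo > hi:
                raise ValueError(f"evalue range for {cat}: lo must be <= hi")
        if not 0 <= self.hit_rate <= 1:
            raise ValueError("hit_rate must be in [0, 1]")
        if self.hits_per_query_mean < 1:
            raise ValueError("hits_per_query_mean must be >= 1")


@dataclass
class ShearResult:
    reads: list[Read]
    #: (original clone id, duplicate clone id) for inserts re-emitted under
    #: a new well, i.e. the planted legitimate contigs.
    duplicate_pairs: list[tuple[str, str]]
    clone_ids: list[str]
    insert_lengths: list[int]


@dataclass
class LibraryPair:
    profile_a: LibraryProfile
    profile_b: LibraryProfile
    reads_a: list[Read]
    reads_b: list[Read]
    hits_a_into_b: pd.DataFrame
    hits_b_into_a: pd.DataFrame
    shared_genome_fraction: float


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    return _BASES[codes].tobytes().decode("ascii")


def generate_genomes(model: GenomeModel, seed: int) -> list[str]:
    """Draw genome sequences: a size class per weight, a uniform length
    within the class, i.i.d. bases at the model's GC fraction."""
    rng = np.random.default_rng(subseed(seed, "genomes"))
    weights = np.array([w for _, _, w in model.size_classes])
    genomes = []
    for _ in range(model.n_genomes):
        ci = rng.choice(len(model.size_classes), p=weights)
        lo, hi, _ = model.size_classes[ci]
        length = int(rng.integers(lo, hi + 1))
        genomes.append(_random_dna(rng, length, model.gc_fraction))
    return genomes


def _well_id(library: str, clone_index: int) -> str:
    per_plate = len(_WELL_ROWS) * _WELL_COLS
    plate = clone_index // per_plate + 1
    within = clone_index % per_plate
    row = _WELL_ROWS[within // _WELL_COLS]
    col = within % _WELL_COLS + 1
    return f"{library}_P{plate:02d}_{row}{col:02d}"


def shear_and_clone(
    genomes: list[str],
    model: CloneModel,
    n_clones: int,
    seed: int,
    library: str = "LIB",
) -> ShearResult:
    """Clone random inserts and emit paired end reads.

    Each clone is a uniform-random insert of length in
    [insert_min_bp, insert_max_bp] from a random genome; the forward read
    covers the 5' end, the reverse read (for paired clones) is the reverse
    complement of the 3' end. With ``duplicate_clone_rate``, a clone
    re-emits a previously drawn insert under a new well id, planting a
    legitimate inter-clone contig. Genomes shorter than the maximum insert
    are skipped with a warning.
    """
    rng = np.random.default_rng(subseed(seed, "reads"))
    usable = [g for g in genomes if len(g) >= model.insert_max_bp]
    if len(usable) < len(genomes):
        logger.warning(
            "skipping %d genome(s) shorter than insert_max_bp",
            len(genomes) - len(usable),
        )
    if not usable:
        raise ValueError("no genome is long enough for the insert range")

    inserts: list[str] = []
    clone_ids: list[str] = []
    duplicate_pairs: list[tuple[str, str]] = []
    for i in range(n_clones):
        clone_id = _well_id(library, i)
        if inserts and rng.random() < model.duplicate_clone_rate:
            j = int(rng.integers(0, len(inserts)))
            inserts.append(inserts[j])
            duplicate_pairs.append((clone_ids[j], clone_id))
        else:
            g = usable[int(rng.integers(0, len(usable)))]
            length = int(rng.integers(model.insert_min_bp,
                                      model.insert_max_bp + 1))
            start = int(rng.integers(0, len(g) - length + 1))
            inserts.append(g[start:start + length])
        clone_ids.append(clone_id)

    reads: list[Read] = []
    for clone_id, insert in zip(clone_ids, inserts):
        lf = int(np.clip(round(rng.normal(model.read_len_mean,
                                          model.read_len_sd)),
                         model.read_len_floor, len(insert)))
        reads.append(Read(f"{clone_id}.F", insert[:lf]))
        if rng.random() < model.paired_fraction:
            lr = int(np.clip(round(rng.normal(model.read_len_mean,
                                              model.read_len_sd)),
                             model.read_len_floor, len(insert)))
            reads.append(Read(f"{clone_id}.R", revcomp(insert[-lr:])))
    return ShearResult(
        reads=reads,
        duplicate_pairs=duplicate_pairs,
        clone_ids=clone_ids,
        insert_lengths=[len(s) for s in inserts],
    )


def simulate_hit_table(
    reads,
    model: HitModel,
    databases: tuple[str, ...] = ("nr",),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a similarity-hit table for a set of queries.

    Each query independently receives hits with probability ``hit_rate``;
    its primary category is multinomial over the composition (a ``none``
    draw leaves the query hitless), with any additional hits drawn from
    the composition renormalized over hit categories. E-values are
    log10-uniform within the category's decade range; descriptions of
    virus-category subjects contain the standard virus keywords.
    """
    rng = np.random.default_rng(subseed(seed, "hits"))
    query_ids = [r if isinstance(r, str) else r.id for r in reads]
    cats = sorted(model.composition)
    probs = np.array([model.composition[c] for c in cats])
    hit_cats = [c for c in cats if c != "none" and model.composition[c] > 0]
    hit_probs = np.array([model.composition[c] for c in hit_cats])
    if hit_probs.sum() > 0:
        hit_probs = hit_probs / hit_probs.sum()
    databases = tuple(databases)

    rows = []
    counter = 0
    for qid in query_ids:
        if rng.random() >= model.hit_rate:
            continue
        primary = cats[int(rng.choice(len(cats), p=probs))]
        if primary == "none":
            continue
        n_hits = 1 + int(rng.poisson(model.hits_per_query_mean - 1.0))
        for h in range(n_hits):
            cat = primary if h == 0 else hit_cats[
                int(rng.choice(len(hit_cats), p=hit_probs))
            ]
            lo, hi = model.evalue_log10_range.get(cat, (-20.0, -1.0))
            evalue = float(10.0 ** rng.uniform(lo, hi))
            descs = _DESCRIPTIONS[cat]
            counter += 1
            rows.append(
                {
                    "query_id": qid,
                    "subject_id": f"{cat}:{counter:06d}",
                    "percent_identity": round(float(rng.uniform(35, 99)), 1),
                    "evalue": evalue,
                    "bit_score": round(-2.0 * math.log10(evalue) + 30.0, 1),
                    "database": databases[int(rng.integers(0, len(databases)))],
                    "subject_description": descs[int(rng.integers(0, len(descs)))],
                    "source_category": cat,
                }
            )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def simulate_gradient(
    n_fractions: int = 12,
    density_range: tuple[float, float] = (1.44, 1.55),
    peak_fractions: tuple[int, ...] = (1, 2, 3, 4),
    seed: int = 0,
    volume_ml: float = 0.3,
    peak_vlp_per_ml: float = 1.583e11,
    background_vlp_per_ml: float = 4e9,
    mass_noise_sd_g: float = 0.0005,
) -> list[GradientFraction]:
    """Simulate a CsCl gradient profile.

    Densities increase monotonically down the gradient across
    ``density_range``; virus-like-particle concentrations peak in
    ``peak_fractions`` (1-based from the top). Fraction mass is density
    times volume plus Gaussian noise (zero noise reproduces the planted
    densities exactly). Defaults emulate twelve 0.3 ml fractions whose top
    four harvested fractions band at ~1.44-1.47 g/ml and total ~1.9e11
    particles.
    """
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    rng = np.random.default_rng(subseed(seed, "gradient"))
    densities = np.linspace(density_range[0], density_range[1], n_fractions)
    peaks = set(peak_fractions)
    fractions = []
    for i, density in enumerate(densities, start=1):
        if i in peaks:
            conc = peak_vlp_per_ml * (0.9 + 0.2 * rng.random())
        else:
            conc = background_vlp_per_ml * (0.5 + rng.random())
        mass = density * volume_ml + (
            rng.normal(0.0, mass_noise_sd_g) if mass_noise_sd_g > 0 else 0.0
        )
        fractions.append(
            GradientFraction(
                index=i, volume_ml=volume_ml, mass_g=float(mass),
                vlp_per_ml=float(conc),
            )
        )
    return fractions


def generate_library_pair(
    shared_genome_fraction: float,
    sizes: tuple[int, int] = (150, 150),
    read_len_means: tuple[float, float] = (300.0, 300.0),
    seed: int = 0,
    n_genomes_per_library: int = 10,
    genome_size_bp: int = 8000,
    gc_fraction: float = 0.45,
    word_size: int = 20,
    names: tuple[str, str] = ("libA", "libB"),
) -> LibraryPair:
    """Two read libraries whose genome pools share a stated fraction, with
    cross-hit tables from :func:`viroshot.compare.naive_cross_search` in
    both directions."""
    if not 0 <= shared_genome_fraction <= 1:
        raise ValueError("shared_genome_fraction must be in [0, 1]")
    rng = np.random.default_rng(subseed(seed, "pair"))
    n_shared = int(round(shared_genome_fraction * n_genomes_per_library))
    shared = [_random_dna(rng, genome_size_bp, gc_fraction)
              for _ in range(n_shared)]
    pools = []
    for _ in range(2):
        unique = [_random_dna(rng, genome_size_bp, gc_fraction)
                  for _ in range(n_genomes_per_library - n_shared)]
        pools.append(shared + unique)

    libraries = []
    for name, pool, n_reads, mean_len in zip(
        names, pools, sizes, read_len_means
    ):
        reads = []
        for i in range(n_reads):
            g = pool[int(rng.integers(0, len(pool)))]
            length = int(np.clip(round(rng.normal(mean_len, 0.1 * mean_len)),
                                 50, len(g)))
            start = int(rng.integers(0, len(g) - length + 1))
            reads.append(Read(f"{name}_r{i:05d}", g[start:start + length]))
        libraries.append(reads)
    reads_a, reads_b = libraries
    return LibraryPair(
        profile_a=LibraryProfile.from_reads(names[0], reads_a),
        profile_b=LibraryProfile.from_reads(names[1], reads_b),
        reads_a=reads_a,
        reads_b=reads_b,
        hits_a_into_b=naive_cross_search(reads_a, reads_b, word_size,
                                         target_name=names[1]),
        hits_b_into_a=naive_cross_search(reads_b, reads_a, word_size,
                                         target_name=names[0]),
        shared_genome_fraction=shared_genome_fraction,
    )


def simulate_assembly_benchmark(
    seed: int = 0,
    n_independent: int = 855,
    n_same_clone_pairs: int = 20,
    n_duplicate_pairs: int = 6,
    n_adjacent_duplicates: int = 5,
    read_len: int = 450,
    library: str = "SYN",
) -> list[Read]:
    """A library with a controlled contig structure for assembly tests.

    Emits ``n_independent`` singleton reads from unrelated random
    sequences, ``n_same_clone_pairs`` clones whose short insert makes the
    forward and reverse reads overlap (same-clone contigs), and
    ``n_duplicate_pairs`` duplicated inserts re-emitted under a different
    well (``n_adjacent_duplicates`` of them in an adjacent well of the
    same plate, the remainder in a distant well). With the defaults the
    read total is 907 and 26 two-read contigs are planted.
    """
    rng = np.random.default_rng(subseed(seed, "benchmark"))
    reads: list[Read] = []
    for i in range(n_independent):
        clone = _well_id(f"{library}s", i)
        reads.append(Read(f"{clone}.F", _random_dna(rng, read_len, 0.45)))
    # short-insert clones: F and R reads overlap in the middle
    for i in range(n_same_clone_pairs):
        clone = _well_id(f"{library}p", i)
        insert = _random_dna(rng, read_len + 250, 0.45)
        reads.append(Read(f"{clone}.F", insert[:read_len]))
        reads.append(Read(f"{clone}.R", revcomp(insert[-read_len:])))
    # duplicated inserts under a different well id
    per_plate = len(_WELL_ROWS) * _WELL_COLS
    for i in range(n_duplicate_pairs):
        insert = _random_dna(rng, read_len + 100, 0.45)
        first_idx = 2 * i * per_plate  # A01 of its own pair of plates
        reads.append(Read(f"{_well_id(f'{library}d', first_idx)}.F",
                          insert[:read_len]))
        if i < n_adjacent_duplicates:
            second_idx = first_idx + 1  # A02: Manhattan distance 1
        else:
            second_idx = first_idx + per_plate - 1  # H12: distant well
        reads.append(Read(f"{_well_id(f'{library}d', second_idx)}.F",
                          insert[:read_len]))
    return reads
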