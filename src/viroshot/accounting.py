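"""Virus-particle and DNA accounting from density-gradient fractions.

Converts bench measurements -- gradient fraction volumes, masses and
epifluorescence particle counts, the DNA yield, and the volume of seawater
processed -- into the quantities a virome study reports: buoyant densities,
total particles recovered, recovery efficiency against historical abundance,
DNA mass per particle (attograms), the implied average genome size for
double-stranded DNA, and how often a single-copy viral gene could appear in
a library of a given total length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

from ._util import round_half_up

AVOGADRO = 6.02214076e23

#: Mean molecular mass of one double-stranded DNA base pair, in daltons.
#: 650 is also in common use; 660 is the default here and configurable.
DALTONS_PER_BP = 660.0


@dataclass(frozen=True)
class GradientFraction:
    """One fraction collected from a buoyant-density gradient (index 1 = top)."""

    index: int
    volume_ml: float
    mass_g: float
    vlp_per_ml: float

    def __post_init__(self) -> None:
        if self.volume_ml <= 0 or self.mass_g <= 0 or self.vlp_per_ml < 0:
            raise ValueError(
                f"fraction {self.index}: volume/mass must be positive"
            )

    @property
    def density(self) -> float:
        """Buoyant density in g/ml, from the mass and volume measurements."""
        return self.mass_g / self.volume_ml

    @property
    def particles(self) -> float:
        return self.vlp_per_ml * self.volume_ml


@dataclass(frozen=True)
class AccountingReport:
    total_particles: float
    dna_mass_g: float
    ag_per_particle: int
    genome_size_bp: float
    genome_size_kb: int
    recovery_pct_range: tuple[float, float]
    recovery_label: str
    expected_gene_copies: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d["recovery_pct_range"] = list(self.recovery_pct_range)
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def __str__(self) -> str:
        lo, hi = self.recovery_pct_range
        return (
            f"particles recovered:     {self.total_particles:.3g}\n"
            f"DNA extracted:           {self.dna_mass_g:.3g} g\n"
            f"DNA per particle:        {self.ag_per_particle} ag\n"
            f"implied dsDNA genome:    {self.genome_size_kb} kb "
            f"({self.genome_size_bp:.0f} bp)\n"
            f"recovery efficiency:     {lo}-{hi} % (~{self.recovery_label})\n"
            f"expected single-copy gene occurrences: "
            f"{self.expected_gene_copies}\n"
        )


def fraction_density(mass_g: float, volume_ml: float) -> float:
    """Density (g/ml) of a gradient fraction from mass and volume."""
    if mass_g <= 0 or volume_ml <= 0:
        raise ValueError("mass and volume must be positive")
    return mass_g / volume_ml


def total_particles(fractions: list[GradientFraction]) -> float:
    """Total particles in the selected fractions: sum of conc x volume."""
    if not fractions:
        raise ValueError("no fractions selected")
    return sum(f.particles for f in fractions)


def dna_per_particle(dna_mass_g: float, n_particles: float) -> int:
    """Average DNA content per particle in attograms (nearest integer)."""
    if dna_mass_g <= 0 or n_particles <= 0:
        raise ValueError("DNA mass and particle count must be positive")
    return round_half_up(dna_mass_g * 1e18 / n_particles)


def genome_size_from_mass(
    mass_ag: float, daltons_per_bp: float = DALTONS_PER_BP
) -> float:
    """Implied double-stranded genome size in bp for a DNA mass in attograms."""
    if mass_ag <= 0:
        raise ValueError("mass must be positive")
    return mass_ag * 1e-18 * AVOGADRO / daltons_per_bp


def recovery_range(
    n_recovered: float,
    volume_filtered_l: float,
    abundance_range: tuple[float, float],
) -> tuple[float, float]:
    """Recovery efficiency (%) against a historical abundance range.

    The high abundance bounds recovery from below and vice versa; both ends
    are reported at one decimal.
    """
    lo_abund, hi_abund = abundance_range
    if min(n_recovered, volume_filtered_l, lo_abund, hi_abund) <= 0:
        raise ValueError("all inputs must be positive")
    if lo_abund > hi_abund:
        raise ValueError("abundance range must be (low, high)")
    low = 100.0 * n_recovered / (volume_filtered_l * hi_abund)
    high = 100.0 * n_recovered / (volume_filtered_l * lo_abund)
    return (round_half_up(low, 1), round_half_up(high, 1))


def expected_gene_copies(total_library_bases: float, genome_size_bp: float) -> float:
    """Times a single-copy gene could appear in the library if every genome
    carried it: total library bases over the mean genome size."""
    if total_library_bases <= 0 or genome_size_bp <= 0:
        raise ValueError("inputs must be positive")
    return total_library_bases / genome_size_bp


def build_report(
    n_particles: float,
    dna_mass_g: float,
    volume_filtered_l: float,
    abundance_range: tuple[float, float],
    total_library_bases: float,
    daltons_per_bp: float = DALTONS_PER_BP,
) -> AccountingReport:
    """Full accounting chain from particle total and DNA yield to the
    derived per-particle, genome-size, recovery and gene-copy figures."""
    ag = dna_per_particle(dna_mass_g, n_particles)
    bp = genome_size_from_mass(ag, daltons_per_bp)
    rec = recovery_range(n_particles, volume_filtered_l, abundance_range)
    label = f"{round_half_up(rec[0])}-{round_half_up(rec[1])}%"
    return AccountingReport(
        total_particles=n_particles,
        dna_mass_g=dna_mass_g,
        ag_per_particle=ag,
        genome_size_bp=bp,
        genome_size_kb=round_half_up(bp / 1000.0),
        recovery_pct_range=rec,
        recovery_label=label,
        expected_gene_copies=round_half_up(
            expected_gene_copies(total_library_bases, bp), 1
        ),
    )
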