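"""Synthetic specimens, references, and climate series.

The field sequences behind the analyses this package implements were
never deposited, so every pipeline stage is exercised on simulated data
with the statistical structure the analyses assume:

* a synthetic COIB259 reference panel (13 Spodoptera taxa plus
  corn-strain and rice-strain consensus amplicons) honouring the
  diagnostic relationships: CS and RS differ at the 1164-equivalent
  site, one taxon pair is deliberately sequence-identical, and all
  other taxa are mutually distinguishable;
* per-site specimen mixtures: COI classes drawn from stated
  probabilities and instantiated as the matching diagnostic bases plus
  a small number of non-diagnostic substitutions (at most two by
  default, matching the observed within-site haplotype similarity);
  Tpi alleles drawn at a stated rice-allele frequency under a
  configurable sex ratio (default 1:1), with male heterozygotes
  encoded as IUPAC ambiguity codes as direct sequencing would show;
* an isolated-site construction placing private haplotypes an exact
  programmed number of mutational steps (default 8) away from the
  mainland cloud;
* weekly climate profiles (incubator / frozen / seasonal / noisy) and
  grids for the ecoclimatic module.

Random mutations never touch the diagnostic positions, so
classification correctness is decoupled from haplotype diversity; the
pools of mutable positions used by mainland noise, rice-allele
divergence, isolated-cloud divergence, and isolated-cloud noise are
mutually disjoint, which makes programmed step counts exact.  Sex is
latent: it drives simulation but is only recorded in the truth table,
never exposed on the specimen record (field larvae are not sexed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .ecoclim import WEEKS_PER_YEAR, WeeklyClimate
from .markers import MarkerOffsets, ReferencePanel, ReferenceSet
from .seqio import SpecimenRecord

__all__ = [
    "PopulationSpec",
    "IsolationSpec",
    "make_references",
    "simulate_population",
    "simulate_isolated_site",
    "simulate_two_clouds",
    "simulate_climate",
    "simulate_climate_grid",
    "DEFAULT_OFFSETS",
]

# Amplicon geometry for the synthetic references (0-based offsets).
COIB_AMPLICON_LEN = 340
TPI_AMPLICON_LEN = 300

DEFAULT_OFFSETS = MarkerOffsets(
    coib259_window=(20, 279),
    coib296_window=(10, 306),
    pos_1164=120,
    pos_1287=243,
    tpie4i4_window=(24, 248),
    pos_tpi183=40,
    tpi_intron_window=(76, 248),
)

# Disjoint pools of mutable Tpi positions (all inside the Tpie4i4
# window, none diagnostic): mainland within-site noise, rice-allele
# intron divergence, isolated-cloud divergence, isolated-cloud noise.
_TPI_NOISE_POOL = tuple(range(80, 140))
_TPI_RALLELE_POOL = tuple(range(140, 150))
_TPI_DIVERGENCE_POOL = tuple(range(150, 200))
_TPI_ISOLATED_NOISE_POOL = tuple(range(200, 240))

# COI within-site noise pool: inside the COIB296 window, excluding the
# diagnostic sites.
_COI_NOISE_POOL = tuple(
    p for p in range(12, 304) if p not in (120, 243)
)

_BASES = "ACGT"
_COI_DIAG = {
    "RS": ("T", "A"),
    "h1": ("A", "A"),
    "h2": ("A", "G"),
    "h3": ("G", "A"),
    "h4": ("G", "G"),
}
# IUPAC code for an unordered base pair (heterozygote double peak).
_IUPAC_PAIR = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("CG"): "S", frozenset("AC"): "M",
}

_PANEL_TAXA = [
    "S_albula", "S_cosmiodes", "S_descoinsi", "S_dolichos", "S_eridania",
    "S_exempta", "S_exigua", "S_latifascia", "S_littoralis", "S_mauritia",
    "S_ornithogalli", "S_praefica", "S_litura",
]
_IDENTICAL_PAIR = ("S_cosmiodes", "S_descoinsi")


@dataclass
class PopulationSpec:
    """Conditions for one simulated collection site."""

    site_id: str
    n_specimens: int
    coi_class_probs: Mapping[str, float] = field(
        default_factory=lambda: {"RS": 0.05, "h1": 0.15, "h2": 0.10,
                                 "h3": 0.10, "h4": 0.60}
    )
    tpi_R_allele_freq: float = 0.02
    male_fraction: float = 0.5
    within_site_mutation_max: int = 2
    frameshift_het_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        probs = dict(self.coi_class_probs)
        if any(p < 0 or p > 1 for p in probs.values()):
            raise ValueError("class probabilities must lie in [0, 1]")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("coi_class_probs must sum to 1")
        if not 0.0 <= self.tpi_R_allele_freq <= 1.0:
            raise ValueError("tpi_R_allele_freq must lie in [0, 1]")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must lie in [0, 1]")


@dataclass
class IsolationSpec:
    """Conditions for an isolated site with private haplotypes a fixed
    number of mutational steps from the mainland."""

    site_id: str
    divergence_steps: int = 8
    n_private_haplotypes: int = 7
    n_specimens: int = 14
    seed: int = 0

    def __post_init__(self):
        if self.divergence_steps < 1:
            raise ValueError("divergence_steps must be >= 1")
        if self.n_private_haplotypes < 1:
            raise ValueError("n_private_haplotypes must be >= 1")


def _random_seq(rng: np.random.Generator, length: int) -> list[str]:
    return [_BASES[i] for i in rng.integers(0, 4, size=length)]


def _substitute(rng: np.random.Generator, seq: list[str], pos: int) -> None:
    current = seq[pos]
    choices = [b for b in _BASES if b != current]
    seq[pos] = choices[rng.integers(0, 3)]


def make_references(seed: int = 0) -> ReferenceSet:
    """Build the synthetic reference set (deterministic per seed).

    The corn-strain COIB amplicon carries A at both diagnostic sites
    (the h1 configuration); the rice-strain amplicon differs at the
    1164 site (T) plus a few non-diagnostic positions.  Panel taxa are
    derived from the corn-strain COIB259 window at 6-12% divergence,
    with one designed identical pair.  The Tpi corn-allele amplicon
    carries C at the 183 site; the rice allele carries T there plus two
    intron substitutions.
    """
    rng = np.random.default_rng(seed)
    offs = DEFAULT_OFFSETS

    cs = _random_seq(rng, COIB_AMPLICON_LEN)
    cs[offs.pos_1164], cs[offs.pos_1287] = "A", "A"
    rs = list(cs)
    rs[offs.pos_1164], rs[offs.pos_1287] = "T", "A"
    for pos in rng.choice(_COI_NOISE_POOL, size=5, replace=False):
        _substitute(rng, rs, int(pos))

    lo, hi = offs.coib259_window
    cs_win, rs_win = "".join(cs[lo:hi]), "".join(rs[lo:hi])
    entries = [
        ("S_frugiperda_CS_consensus", cs_win),
        ("S_frugiperda_RS_consensus", rs_win),
    ]
    taxa_seqs: dict[str, str] = {}
    for taxon in _PANEL_TAXA:
        if taxon == _IDENTICAL_PAIR[1]:
            taxa_seqs[taxon] = taxa_seqs[_IDENTICAL_PAIR[0]]
            continue
        while True:
            seq = cs[lo:hi].copy()
            n_subs = int(rng.integers(16, 31))
            for pos in rng.choice(len(seq), size=n_subs, replace=False):
                _substitute(rng, seq, int(pos))
            s = "".join(seq)
            if s not in taxa_seqs.values() and s not in (cs_win, rs_win):
                break
        taxa_seqs[taxon] = s
    entries += [(t, taxa_seqs[t]) for t in _PANEL_TAXA]

    panel = ReferencePanel(entries=entries, consensus_cs=cs_win, consensus_rs=rs_win)

    tpi_c = _random_seq(rng, TPI_AMPLICON_LEN)
    tpi_c[offs.pos_tpi183] = "C"
    tpi_r = list(tpi_c)
    tpi_r[offs.pos_tpi183] = "T"
    for pos in rng.choice(_TPI_RALLELE_POOL, size=2, replace=False):
        _substitute(rng, tpi_r, int(pos))

    return ReferenceSet(
        coib_amplicon_cs="".join(cs),
        coib_amplicon_rs="".join(rs),
        tpi_amplicon_c="".join(tpi_c),
        tpi_amplicon_r="".join(tpi_r),
        panel=panel,
        offsets=offs,
    )


def _merge_alleles(a: str, b: str) -> str:
    """Direct-sequencing view of a heterozygote: IUPAC code at every
    position where the two alleles differ."""
    out = []
    for x, y in zip(a, b):
        out.append(x if x == y else _IUPAC_PAIR[frozenset((x, y))])
    return "".join(out)


def simulate_population(
    spec: PopulationSpec, refs: ReferenceSet
) -> tuple[list[SpecimenRecord], pd.DataFrame]:
    """Simulate one collection site; returns records plus the truth
    table of latent variables (sex, true classes, allele draws)."""
    rng = np.random.default_rng(spec.seed)
    offs = refs.offsets
    classes = list(spec.coi_class_probs)
    probs = np.array([spec.coi_class_probs[c] for c in classes], dtype=float)
    probs = probs / probs.sum()

    records, truth = [], []
    ilo, ihi = offs.tpi_intron_window
    for i in range(spec.n_specimens):
        spec_id = f"{spec.site_id}_{i:04d}"
        male = bool(rng.random() < spec.male_fraction)

        coi_class = classes[int(rng.choice(len(classes), p=probs))]
        backbone = refs.coib_amplicon_rs if coi_class == "RS" else refs.coib_amplicon_cs
        coib = list(backbone)
        coib[offs.pos_1164], coib[offs.pos_1287] = _COI_DIAG[coi_class]
        k = int(rng.integers(0, spec.within_site_mutation_max + 1))
        if k:
            for pos in rng.choice(_COI_NOISE_POOL, size=k, replace=False):
                _substitute(rng, coib, int(pos))

        n_alleles = 2 if male else 1
        alleles = [
            "R" if rng.random() < spec.tpi_R_allele_freq else "C"
            for _ in range(n_alleles)
        ]
        hap = {"C": refs.tpi_amplicon_c, "R": refs.tpi_amplicon_r}
        if len(set(alleles)) == 2:
            tpi_seq = _merge_alleles(hap["C"], hap["R"])
        else:
            tpi_seq = hap[alleles[0]]
        tpi = list(tpi_seq)
        k = int(rng.integers(0, spec.within_site_mutation_max + 1))
        if k:
            candidates = [p for p in _TPI_NOISE_POOL if tpi[p] in _BASES]
            for pos in rng.choice(candidates, size=k, replace=False):
                _substitute(rng, tpi, int(pos))

        frameshift = bool(
            male and rng.random() < spec.frameshift_het_fraction
        )
        if frameshift:
            start = int(rng.integers(ilo + 5, ihi - 15))
            codes = list(_IUPAC_PAIR.values())
            for j in range(8):
                tpi[start + j] = codes[int(rng.integers(0, len(codes)))]

        records.append(
            SpecimenRecord(
                specimen_id=spec_id,
                site_id=spec.site_id,
                sequences={"COIB": "".join(coib), "TPI": "".join(tpi)},
            )
        )
        truth.append(
            {
                "specimen_id": spec_id,
                "site_id": spec.site_id,
                "sex": "M" if male else "F",
                "coi_class": coi_class,
                "tpi_genotype": "".join(sorted(alleles)),
                "frameshift_het": frameshift,
            }
        )
    return records, pd.DataFrame(truth)


def simulate_isolated_site(
    spec: IsolationSpec, refs: ReferenceSet
) -> tuple[list[SpecimenRecord], pd.DataFrame]:
    """Simulate an isolated site whose Tpi haplotypes sit exactly
    ``divergence_steps`` substitutions from the mainland corn-allele
    haplotype, with at most two further within-site steps per private
    haplotype.

    The divergence substitutions use a position pool disjoint from the
    mainland noise pool, so the programmed step count is exact by
    construction.  Raises when the requested steps exceed the available
    non-diagnostic positions.
    """
    if spec.divergence_steps > len(_TPI_DIVERGENCE_POOL):
        raise ValueError(
            f"divergence_steps={spec.divergence_steps} exceeds the "
            f"{len(_TPI_DIVERGENCE_POOL)} available non-diagnostic positions"
        )
    rng = np.random.default_rng(spec.seed)
    base = list(refs.tpi_amplicon_c)
    div_pos = rng.choice(
        _TPI_DIVERGENCE_POOL, size=spec.divergence_steps, replace=False
    )
    for pos in div_pos:
        _substitute(rng, base, int(pos))

    haplotypes = ["".join(base)]
    used: list[int] = []
    for j in range(1, spec.n_private_haplotypes):
        extra = 1 + (j - 1) % 2  # alternate 1- and 2-step variants
        variant = list(base)
        candidates = [p for p in _TPI_ISOLATED_NOISE_POOL if p not in used]
        pos = rng.choice(candidates, size=extra, replace=False)
        for p in pos:
            _substitute(rng, variant, int(p))
        used.extend(int(p) for p in pos)
        haplotypes.append("".join(variant))

    records, truth = [], []
    for i in range(spec.n_specimens):
        hap_idx = i % spec.n_private_haplotypes
        spec_id = f"{spec.site_id}_{i:04d}"
        records.append(
            SpecimenRecord(
                specimen_id=spec_id,
                site_id=spec.site_id,
                sequences={"TPI": haplotypes[hap_idx]},
            )
        )
        truth.append(
            {"specimen_id": spec_id, "site_id": spec.site_id,
             "haplotype_index": hap_idx}
        )
    return records, pd.DataFrame(truth)


def simulate_two_clouds(
    seed: int = 0,
    n_mainland: int = 30,
    divergence_steps: int = 8,
    n_private_haplotypes: int = 7,
) -> tuple[list[SpecimenRecord], ReferenceSet]:
    """Convenience scenario: a mainland site plus an isolated site with
    private haplotypes at a programmed separation — the pattern that
    distinguishes an interbreeding population cloud from a genetically
    isolated one."""
    refs = make_references(seed)
    mainland_spec = PopulationSpec(
        site_id="mainland",
        n_specimens=n_mainland,
        tpi_R_allele_freq=0.0,
        male_fraction=0.0,  # haploid Tpi reads: unambiguous haplotypes
        seed=seed + 1,
    )
    mainland, _ = simulate_population(mainland_spec, refs)
    island_spec = IsolationSpec(
        site_id="island",
        divergence_steps=divergence_steps,
        n_private_haplotypes=n_private_haplotypes,
        n_specimens=2 * n_private_haplotypes,
        seed=seed + 2,
    )
    island, _ = simulate_isolated_site(island_spec, refs)
    return mainland + island, refs


def simulate_climate(
    profile: str,
    seed: int = 0,
    mean_T: float = 24.0,
    amp_T: float = 8.0,
    mean_SM: float = 1.0,
    amp_SM: float = 0.4,
    noise_T: float = 1.0,
    noise_SM: float = 0.1,
    phase_weeks: float = 0.0,
) -> WeeklyClimate:
    """Build a 52-week climate series.

    Profiles: ``incubator`` (optimal constant conditions), ``frozen``
    (constant temperature below the development threshold),
    ``seasonal`` (sinusoidal temperature and soil moisture with the
    given means/amplitudes/phase), ``noisy`` (seasonal plus i.i.d.
    weekly Gaussian noise).  Deterministic per seed.
    """
    weeks = np.arange(WEEKS_PER_YEAR)
    if profile == "incubator":
        return WeeklyClimate(np.full(52, 27.0), np.full(52, 1.0))
    if profile == "frozen":
        return WeeklyClimate(np.full(52, 4.0), np.full(52, 1.0))
    if profile in ("seasonal", "noisy"):
        angle = 2 * math.pi * (weeks - phase_weeks) / WEEKS_PER_YEAR
        T = mean_T + amp_T * np.sin(angle)
        SM = mean_SM + amp_SM * np.sin(angle + math.pi / 2)
        if profile == "noisy":
            rng = np.random.default_rng(seed)
            T = T + rng.normal(0.0, noise_T, size=52)
            SM = SM + rng.normal(0.0, noise_SM, size=52)
        return WeeklyClimate(T, np.maximum(SM, 0.0))
    raise ValueError(f"unknown climate profile: {profile!r}")


def simulate_climate_grid(
    nrows: int = 4,
    ncols: int = 5,
    seed: int = 0,
    missing_fraction: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """A (52, nrows, ncols) grid pair mixing profiles across cells,
    with a fraction of cells missing (all-NaN)."""
    rng = np.random.default_rng(seed)
    T = np.empty((WEEKS_PER_YEAR, nrows, ncols))
    SM = np.empty_like(T)
    profiles = ["incubator", "frozen", "seasonal", "noisy"]
    for i in range(nrows):
        for j in range(ncols):
            prof = profiles[int(rng.integers(0, len(profiles)))]
            clim = simulate_climate(
                prof,
                seed=int(rng.integers(0, 2**31 - 1)),
                mean_T=float(rng.uniform(10, 30)),
            )
            if rng.random() < missing_fraction:
                T[:, i, j] = np.nan
                SM[:, i, j] = np.nan
            else:
                T[:, i, j] = clim.temperature
                SM[:, i, j] = clim.soil_moisture
    return T, SM
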