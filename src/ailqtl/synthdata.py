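"""Advanced-intercross-line simulator.

Emulates a (DA x PVG.1AV1)-style AIL maintained for ``n_generations``
generations of random intercrossing (generation 2 = F2, generation 10 = G10),
with a configurable number of breeding couples per generation. Meioses follow
the Haldane (no-interference) map function on cM positions derived from the
physical Mb map at a uniform, configurable rate (default 1 cM/Mb). Trait
architecture is expressed as genotype-class effects at arbitrary QTL
positions: quantitative traits are sums of class means, a shared per-family
effect, a sex effect and Gaussian noise; the binary incidence trait is drawn
per individual from a genotype-dependent penetrance.

The default desk-scale fixture (:func:`make_eae23_fixture`) reproduces the
statistical structure of the mapped rat cohort: 20 microsatellite markers over
13.9-81.6 Mb of chromosome 17 (including the 33.3-42.7 Mb non-polymorphic
gap), 428 tenth-generation animals bred from 50 couples, one
dominant/transgressive locus at 47.3 Mb and one heterotic locus at 62.0 Mb
(heterozygote penetrance ~1.6x homozygote), and overall incidence near 0.29.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import (
    GENOTYPE_CODES,
    GeneticMap,
    GenotypeMatrix,
    PhenotypeTable,
    QUANTITATIVE_TRAITS,
)

__all__ = [
    "QtlSpec",
    "SimConfig",
    "Pedigree",
    "simulate_ail",
    "derive_cm_positions",
    "haldane_recombination_fraction",
    "make_eae23_map",
    "make_eae23_fixture",
    "EAE23_QTL_A_MB",
    "EAE23_QTL_B_MB",
]

# Trait-level noise scales (units of each trait), multiplied by
# SimConfig.residual_sd. ONS/DUR are days, MAX a 0-4 score, CUM score-days,
# WL percent of initial weight.
BASE_TRAIT_SD: Mapping[str, float] = {
    "ONS": 5.0,
    "MAX": 0.8,
    "DUR": 5.0,
    "CUM": 4.0,
    "WL": 2.5,
}

_QTL_MODES = ("additive", "dominant_A", "dominant_B", "heterosis")


@dataclass(frozen=True)
class QtlSpec:
    """Genotype-class effects of one locus on one trait.

    For quantitative traits the three effects are class means (trait units)
    added to the baseline; for ``trait="INC"`` they are penetrance shifts
    added to the baseline penetrance. ``mode`` documents the allelic
    architecture and is validated against the effect pattern where it is
    well defined (heterosis requires the heterozygote strictly outside the
    homozygote range).
    """

    position: float  # Mb
    mode: str
    trait: str
    effect_aa: float
    effect_ab: float
    effect_bb: float

    def __post_init__(self) -> None:
        if self.mode not in _QTL_MODES:
            raise ValueError(f"mode must be one of {_QTL_MODES}")
        eff = (self.effect_aa, self.effect_ab, self.effect_bb)
        if not all(math.isfinite(e) for e in eff):
            raise ValueError("QTL effects must be finite")
        if self.mode == "heterosis":
            lo, hi = min(self.effect_aa, self.effect_bb), max(
                self.effect_aa, self.effect_bb
            )
            if lo <= self.effect_ab <= hi:
                raise ValueError(
                    "heterosis requires the heterozygote effect strictly "
                    "outside the homozygote range"
                )

    @property
    def effects(self) -> np.ndarray:
        return np.array([self.effect_aa, self.effect_ab, self.effect_bb])


@dataclass(frozen=True)
class SimConfig:
    """Breeding design, map and trait architecture for one simulation.

    ``family_effect_sd`` and ``sex_effect`` are expressed as multiples of
    each trait's residual SD so that one knob spans traits measured in days,
    scores and percent; ``residual_sd`` is a global multiplier on the
    per-trait noise scales.
    """

    map: GeneticMap
    qtl_specs: tuple[QtlSpec, ...] = ()
    n_generations: int = 10
    n_couples: int = 50
    n_offspring: int = 4
    n_final: int | None = None  # total final-generation individuals
    family_effect_sd: float = 0.0
    residual_sd: float = 1.0
    base_penetrance: float = 0.29
    sex_effect: float = 0.0
    cm_per_mb: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_generations < 2:
            raise ValueError("n_generations must be >= 2 (2 = F2)")
        if self.n_couples < 1:
            raise ValueError("n_couples must be >= 1")
        if self.n_offspring < 1:
            raise ValueError("n_offspring must be >= 1")
        if self.family_effect_sd < 0:
            raise ValueError("family_effect_sd must be >= 0")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        if not 0.0 <= self.base_penetrance <= 1.0:
            raise ValueError("base_penetrance must lie in [0, 1]")
        if self.cm_per_mb <= 0:
            raise ValueError("cm_per_mb must be > 0")
        lo, hi = float(self.map.pos_mb[0]), float(self.map.pos_mb[-1])
        for q in self.qtl_specs:
            if not lo <= q.position <= hi:
                raise ValueError(
                    f"QTL at {q.position} Mb outside map span [{lo}, {hi}]"
                )
        # penetrance must stay in [0,1] for every multilocus genotype
        inc = [q for q in self.qtl_specs if q.trait == "INC"]
        if inc:
            worst_lo = self.base_penetrance + sum(q.effects.min() for q in inc)
            worst_hi = self.base_penetrance + sum(q.effects.max() for q in inc)
            if worst_lo < -1e-9 or worst_hi > 1 + 1e-9:
                raise ValueError(
                    "penetrance (base + INC shifts) escapes [0, 1] for some "
                    "genotype combination"
                )


@dataclass(frozen=True)
class Pedigree:
    """All simulated individuals: id, generation, sire, dam, sex, family.

    Founders (generation 0) have empty sire/dam; every non-founder has
    exactly one sire and one dam from the previous generation. ``family``
    is the sibship (breeding couple) identifier.
    """

    table: pd.DataFrame

    @property
    def final_generation(self) -> int:
        return int(self.table["generation"].max())


# ---------------------------------------------------------------------------
# genetic map utilities
# ---------------------------------------------------------------------------


def derive_cm_positions(gmap: GeneticMap, rate: float = 1.0) -> GeneticMap:
    """Attach genetic positions cM = Mb x rate to a physical map."""
    if not (rate > 0 and math.isfinite(rate)):
        raise ValueError("cM/Mb rate must be positive and finite")
    return replace(gmap, pos_cm=gmap.pos_mb * rate)


def haldane_recombination_fraction(d_cm) -> np.ndarray | float:
    """Recombination fraction for a distance in cM under Haldane's map."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, float) / 100.0))


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------


def _meioses(rng, hap_a: np.ndarray, hap_b: np.ndarray, rec: np.ndarray
             ) -> np.ndarray:
    """Vectorized gametes: one per row of the (n, L) haplotype-pair arrays.

    ``rec`` holds the L-1 adjacent recombination fractions. Crossovers occur
    independently in each interval (no interference, matching Haldane).
    """
    n, L = hap_a.shape
    start = rng.random((n, 1)) < 0.5
    if L > 1:
        switches = rng.random((n, L - 1)) < rec
        # parity of crossover count up to each locus picks the source strand
        src = np.logical_xor.accumulate(
            np.concatenate([start, switches], axis=1), axis=1
        )
    else:
        src = start
    return np.where(src, hap_b, hap_a)


def simulate_ail(config: SimConfig):
    """Gene-drop an AIL and phenotype its final generation.

    Returns ``(Pedigree, GenotypeMatrix, PhenotypeTable)``; the genotype and
    phenotype tables cover the final generation only (the mapped cohort).
    Deterministic for a fixed config and seed.
    """
    rng = np.random.default_rng(config.seed)
    gmap = config.map

    # augmented locus list: markers plus (hidden) QTL positions
    marker_pos = gmap.pos_mb
    qtl_pos = sorted({q.position for q in config.qtl_specs})
    all_pos = np.unique(np.concatenate([marker_pos, np.asarray(qtl_pos)]))
    marker_idx = np.searchsorted(all_pos, marker_pos)
    qtl_idx = {p: int(np.searchsorted(all_pos, p)) for p in qtl_pos}

    d_cm = np.diff(all_pos) * config.cm_per_mb
    rec = np.asarray(haldane_recombination_fraction(d_cm))

    L = all_pos.size
    nc = config.n_couples

    ped_rows: list[tuple] = []

    # generation 0: founder couples, one fully-DA (A) and one fully-PVG (B)
    # parent each; alternate which strain supplies the sire.
    sire_h1 = np.zeros((nc, L), np.int8)
    sire_h2 = np.zeros((nc, L), np.int8)
    dam_h1 = np.ones((nc, L), np.int8)
    dam_h2 = np.ones((nc, L), np.int8)
    sire_ids = [f"G0-S{i}" for i in range(nc)]
    dam_ids = [f"G0-D{i}" for i in range(nc)]
    for i in range(nc):
        ped_rows.append((sire_ids[i], 0, "", "", "M", f"F0-{i}"))
        ped_rows.append((dam_ids[i], 0, "", "", "F", f"F0-{i}"))

    couples = (sire_h1, sire_h2, dam_h1, dam_h2, sire_ids, dam_ids)

    final_ids: list[str] = []
    final_h1 = final_h2 = None
    final_family: list[str] = []
    final_sex = None

    for gen in range(1, config.n_generations + 1):
        last = gen == config.n_generations
        if last:
            n_total = (
                config.n_final
                if config.n_final is not None
                else nc * config.n_offspring
            )
        else:
            n_total = nc * config.n_offspring
        # distribute offspring over couples as evenly as possible
        base, extra = divmod(n_total, nc)
        per_couple = np.full(nc, base, int)
        per_couple[:extra] += 1
        if np.any(per_couple == 0):
            per_couple = np.maximum(per_couple, 1)

        s1, s2, d1, d2, sids, dids = couples
        couple_of = np.repeat(np.arange(nc), per_couple)
        g_s1, g_s2 = s1[couple_of], s2[couple_of]
        g_d1, g_d2 = d1[couple_of], d2[couple_of]
        hap_pat = _meioses(rng, g_s1, g_s2, rec)
        hap_mat = _meioses(rng, g_d1, g_d2, rec)
        sex = np.where(rng.random(couple_of.size) < 0.5, "M", "F")
        ids = [f"G{gen}-{i}" for i in range(couple_of.size)]
        fams = [f"G{gen}F{c}" for c in couple_of]
        for i, ind in enumerate(ids):
            c = couple_of[i]
            ped_rows.append((ind, gen, sids[c], dids[c], sex[i], fams[i]))

        if last:
            final_ids, final_family, final_sex = ids, fams, sex
            final_h1, final_h2 = hap_pat, hap_mat
            break

        couples = _pair_couples(
            rng, nc, hap_pat, hap_mat, ids, fams, sex
        )

    pedigree = Pedigree(
        pd.DataFrame(
            ped_rows,
            columns=["id", "generation", "sire", "dam", "sex", "family"],
        )
    )

    geno_codes = (final_h1 + final_h2)[:, marker_idx]  # 0/1/2
    geno_str = np.array(GENOTYPE_CODES, dtype=object)[geno_codes]
    genotypes = GenotypeMatrix(
        pd.DataFrame(geno_str, index=pd.Index(final_ids, name="id"),
                     columns=list(gmap.markers))
    )

    qtl_geno = {
        p: (final_h1 + final_h2)[:, qtl_idx[p]] for p in qtl_pos
    }
    phenos = _phenotypes(
        rng, config, final_ids, final_family, final_sex, qtl_geno
    )
    return pedigree, genotypes, phenos


def _pair_couples(rng, nc, hap_pat, hap_mat, ids, fams, sex):
    """Random male-female pairing with sibling-mating avoidance."""
    males = [i for i, s in enumerate(sex) if s == "M"]
    females = [i for i, s in enumerate(sex) if s == "F"]
    if len(males) < nc or len(females) < nc:
        raise RuntimeError(
            f"not enough offspring to form {nc} couples "
            f"({len(males)} males, {len(females)} females); "
            "increase n_offspring"
        )
    males = list(rng.permutation(males)[:nc])
    best = None
    for _ in range(50):
        fem = list(rng.permutation(females)[:nc])
        clashes = sum(fams[m] == fams[f] for m, f in zip(males, fem))
        if best is None or clashes < best[0]:
            best = (clashes, fem)
        if clashes == 0:
            break
    fem = best[1]
    mi = np.array(males)
    fi = np.array(fem)
    return (
        hap_pat[mi], hap_mat[mi], hap_pat[fi], hap_mat[fi],
        [ids[i] for i in males], [ids[i] for i in fem],
    )


def _phenotypes(rng, config, ids, families, sex, qtl_geno):
    """Draw EAE traits for the final generation."""
    n = len(ids)
    by_trait: dict[str, list[QtlSpec]] = {}
    for q in config.qtl_specs:
        by_trait.setdefault(q.trait, []).append(q)

    def class_shift(trait: str) -> np.ndarray:
        shift = np.zeros(n)
        for q in by_trait.get(trait, []):
            shift += q.effects[qtl_geno[q.position]]
        return shift

    # family effects: one standard-normal draw per family, scaled per trait
    fam_labels = pd.Index(families)
    uniq = fam_labels.unique()
    fam_z = dict(zip(uniq, rng.normal(size=uniq.size)))
    z = np.array([fam_z[f] for f in families])
    male = np.asarray(sex) == "M"

    def noise(trait: str, size: int) -> np.ndarray:
        return rng.normal(0.0, BASE_TRAIT_SD[trait] * config.residual_sd, size)

    def fam_sex(trait: str) -> np.ndarray:
        sd = BASE_TRAIT_SD[trait] * config.residual_sd
        return (
            z * config.family_effect_sd * sd
            + male.astype(float) * config.sex_effect * sd
        )

    pen = np.clip(config.base_penetrance + class_shift("INC"), 0.0, 1.0)
    inc = (rng.random(n) < pen).astype(int)
    aff = inc == 1

    ons = np.full(n, np.nan)
    ons_raw = 18.0 + class_shift("ONS") + fam_sex("ONS") + noise("ONS", n)
    ons[aff] = np.clip(np.round(ons_raw[aff]), 10, 35)

    mx = np.zeros(n)
    mx_raw = 2.2 + class_shift("MAX") + fam_sex("MAX") + noise("MAX", n)
    mx[aff] = np.clip(mx_raw[aff], 0.25, 4.0)

    dur = np.zeros(n)
    dur_raw = 12.0 + class_shift("DUR") + fam_sex("DUR") + noise("DUR", n)
    dur[aff] = np.clip(dur_raw[aff], 1.0, 35.0)
    # symptoms cannot outlast the window that remains after onset
    dur[aff] = np.minimum(dur[aff], 36.0 - ons[aff])

    cum = np.zeros(n)
    cum_raw = 0.5 * mx * dur + class_shift("CUM") + noise("CUM", n)
    cum[aff] = np.maximum(cum_raw[aff], 0.25)

    wl = 1.5 + 9.0 * inc + class_shift("WL") + fam_sex("WL") + noise("WL", n)
    wl = np.maximum(wl, 0.0)

    table = pd.DataFrame(
        {
            "sex": list(sex),
            "family": families,
            "INC": inc,
            "ONS": ons,
            "MAX": np.round(mx, 4),
            "DUR": np.round(dur, 4),
            "CUM": np.round(cum, 4),
            "WL": np.round(wl, 4),
        },
        index=pd.Index(ids, name="id"),
    )
    return PhenotypeTable(table)


# ---------------------------------------------------------------------------
# default desk-scale fixture
# ---------------------------------------------------------------------------

EAE23_QTL_A_MB = 47.3  # dominant/transgressive locus (PVG allele promotes)
EAE23_QTL_B_MB = 62.0  # heterotic locus (heterozygote predisposed)

_EAE23_MARKERS = (
    ("D17Mit3", 13.9),
    ("D17Rat47", 17.5),
    ("D17Mit5", 21.0),
    ("D17Rat22", 24.3),
    ("D17Rat8", 27.6),
    ("D17Got33", 30.4),
    ("D17Rat12", 33.3),
    ("D17Got49", 42.7),
    ("D17Got60", 45.0),
    ("D17Got45", 47.3),
    ("D17Rat90", 50.8),
    ("D17Got88", 54.0),
    ("D17Rat51", 57.2),
    ("D17Got101", 59.5),
    ("D17Got120", 61.8),
    ("D17Got70", 62.3),
    ("D17Rat67", 66.0),
    ("D17Mit9", 70.5),
    ("D17Rat37", 75.8),
    ("D17Rat154", 81.6),
)


def make_eae23_map() -> GeneticMap:
    """20-marker map over 13.9-81.6 Mb of rat chromosome 17.

    Marker order and the anchor positions (the 33.3-42.7 Mb non-polymorphic
    gap, the 47.3 Mb and 61.8/62.3 Mb peak markers, the 27.6 and 75.8 Mb
    congenic boundary markers) follow the mapped cohort; the remaining
    positions fill the region at realistic microsatellite spacing.
    """
    names, pos = zip(*_EAE23_MARKERS)
    return GeneticMap(
        markers=names, chrom=("17",) * len(names), pos_mb=np.array(pos)
    )


def make_eae23_qtl_specs() -> tuple[QtlSpec, ...]:
    """Two-locus trait architecture for the default fixture.

    Locus A (47.3 Mb): PVG (B) alleles promote disease dominantly, i.e.
    transgressive protection of the DA homozygote. Locus B (62.0 Mb):
    heterosis, heterozygotes predisposed, penetrance ratio ~1.6.
    """
    a, b = EAE23_QTL_A_MB, EAE23_QTL_B_MB
    return (
        QtlSpec(a, "dominant_B", "INC", -0.12, 0.06, 0.06),
        QtlSpec(b, "heterosis", "INC", -0.0675, 0.0675, -0.0675),
        QtlSpec(a, "dominant_B", "ONS", 5.0, -2.5, -2.5),
        QtlSpec(b, "heterosis", "ONS", 2.0, -4.0, 2.0),
        QtlSpec(a, "dominant_B", "MAX", -0.85, 0.42, 0.42),
        QtlSpec(b, "heterosis", "MAX", -0.45, 0.45, -0.45),
        QtlSpec(a, "dominant_B", "DUR", -5.0, 2.5, 2.5),
        QtlSpec(b, "heterosis", "DUR", -3.0, 3.0, -3.0),
        QtlSpec(a, "dominant_B", "WL", -2.4, 1.2, 1.2),
        QtlSpec(b, "heterosis", "WL", -1.2, 1.2, -1.2),
    )


def make_eae23_config(seed: int = 1, **overrides) -> SimConfig:
    defaults = dict(
        map=make_eae23_map(),
        qtl_specs=make_eae23_qtl_specs(),
        n_generations=10,
        n_couples=50,
        n_offspring=4,
        n_final=428,
        family_effect_sd=0.3,
        residual_sd=1.0,
        base_penetrance=0.275,
        sex_effect=0.0,
        cm_per_mb=1.0,
        seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


def make_eae23_fixture(seed: int = 1):
    """Default desk-scale cohort: 428 G10 individuals, two linked QTLs."""
    return simulate_ail(make_eae23_config(seed))
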