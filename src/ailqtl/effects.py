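"""Allelic effects at peak markers.

Stratifies the cohort by genotype class at a marker, tests class
differences nonparametrically (Kruskal-Wallis across the three classes,
pairwise Mann-Whitney for quantitative contrasts, Fisher's exact test for
incidence contrasts), applies Bonferroni control to the trait-level
confirmation tests, and classifies the allelic architecture:

* ``heterosis`` -- the heterozygote differs from both homozygotes in the
  same direction;
* ``dominant_A`` / ``dominant_B`` -- the heterozygote sides with one
  homozygote and both differ from the other;
* ``additive`` -- the homozygotes differ and the heterozygote sits between
  them;
* ``none`` -- no significant pattern.

Classification contrasts use raw pairwise p-values at the stated alpha; the
Bonferroni multiplier applies to the marker x phenotype family of
Kruskal-Wallis confirmation tests, the most conservative reading of the
published correction. A locus is flagged transgressive when the class
carrying the resistant-strain (PVG, allele B) genotype shows the more
severe phenotype.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .formats import (
    ALL_TRAITS,
    GENOTYPE_CODES,
    GenotypeMatrix,
    PhenotypeTable,
    QUANTITATIVE_TRAITS,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AllelicEffect",
    "stratify_and_test",
    "predict_congenic",
    "kruskal_wallis",
    "mann_whitney",
    "fisher_exact",
    "bonferroni",
    "EXACT_MW_MAX_N",
]

#: Combined sample size at or below which Mann-Whitney is computed by full
#: enumeration (tie-safe); larger samples use the tie-corrected normal
#: approximation.
EXACT_MW_MAX_N = 12

_SEVERITY_SIGN = {  # +1: larger value = more severe disease
    "INC": 1, "MAX": 1, "DUR": 1, "CUM": 1, "WL": 1, "ONS": -1,
}


# ---------------------------------------------------------------------------
# nonparametric primitives
# ---------------------------------------------------------------------------


def kruskal_wallis(*groups: Sequence[float]) -> float:
    """Tie-corrected Kruskal-Wallis p-value across >= 2 groups."""
    gs = [np.asarray(g, float) for g in groups]
    if len(gs) < 2 or any(g.size == 0 for g in gs):
        raise ValueError("Kruskal-Wallis needs >= 2 non-empty groups")
    flat = np.concatenate(gs)
    if np.all(flat == flat[0]):  # degenerate: all values identical
        return 1.0
    try:
        return float(stats.kruskal(*gs).pvalue)
    except ValueError:
        return 1.0


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney p: exact enumeration for combined n <= 12,
    tie-corrected normal approximation otherwise."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("Mann-Whitney needs two non-empty groups")
    if x.size == 1 and y.size == 1:
        return 1.0  # a single observation per group cannot discriminate
    if x.size + y.size <= EXACT_MW_MAX_N:
        return _mw_exact(x, y)
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        .pvalue
    )


def _mw_exact(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided p by enumerating all group assignments (midranks, so
    ties are handled exactly)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = x.size
    obs = ranks[:n1].sum()
    mean = n1 * (pooled.size + 1) / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(pooled.size), n1):
        total += 1
        s = ranks[list(combo)].sum()
        if abs(s - mean) >= abs(obs - mean) - 1e-9:
            count += 1
    return count / total


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table."""
    t = np.asarray(table, int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("Fisher's exact test needs a non-negative 2x2 table")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def bonferroni(p: float, m_tests: int) -> float:
    """p_adj = min(1, p x m); never decreases a p-value."""
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    return min(1.0, p * m_tests)


# ---------------------------------------------------------------------------
# allelic-effect stratification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AllelicEffect:
    """Per-genotype-class summaries and tests at one marker."""

    marker: str
    class_n: Mapping[str, int]
    class_incidence: Mapping[str, float]
    summaries: pd.DataFrame  # (trait, class) -> mean/sd/median
    kw_p: Mapping[str, float]  # trait -> raw Kruskal-Wallis p
    kw_p_adj: Mapping[str, float]  # Bonferroni-adjusted
    pairwise_p: Mapping[str, Mapping[tuple[str, str], float]]
    classification: Mapping[str, str]  # trait -> architecture label
    transgressive: Mapping[str, bool]
    alpha: float

    def classification_for(self, trait: str) -> str:
        return self.classification[trait]

    @property
    def locus_classification(self) -> str:
        """Modal architecture label across traits.

        The label assigned most often among the per-trait classifications,
        ignoring ``none``; ties or no significant trait give ``none``. All
        clinical traits reflect the same locus, so the vote pools power
        across correlated phenotypes.
        """
        from collections import Counter

        votes = Counter(
            c for c in self.classification.values() if c != "none"
        )
        if not votes:
            return "none"
        ranked = votes.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            return "none"
        return ranked[0][0]

    @property
    def locus_transgressive(self) -> bool:
        """Transgression by majority vote across traits."""
        flags = list(self.transgressive.values())
        return sum(flags) > len(flags) / 2


def _classify(values: dict[str, float], pw: dict[tuple[str, str], float],
              alpha: float) -> str:
    """Architecture label from class locations and pairwise significance."""
    present = [g for g in GENOTYPE_CODES if g in values]
    if len(present) < 3:
        # two-class data: only a dominance-style or null statement possible
        if len(present) == 2:
            pair = tuple(sorted(present))
            if pw.get(pair, 1.0) <= alpha:
                return "additive"
        return "none"
    vAA, vAB, vBB = values["AA"], values["AB"], values["BB"]
    sig = {k: p <= alpha for k, p in pw.items()}
    s_ab_aa = sig.get(("AA", "AB"), False)
    s_ab_bb = sig.get(("AB", "BB"), False)
    s_aa_bb = sig.get(("AA", "BB"), False)
    het_out = (vAB > max(vAA, vBB)) or (vAB < min(vAA, vBB))
    if s_ab_aa and s_ab_bb and het_out:
        return "heterosis"
    if s_ab_bb and s_aa_bb and not s_ab_aa:
        return "dominant_A"  # AB sides with AA
    if s_ab_aa and s_aa_bb and not s_ab_bb:
        return "dominant_B"  # AB sides with BB
    if s_aa_bb and min(vAA, vBB) <= vAB <= max(vAA, vBB):
        return "additive"
    return "none"


def stratify_and_test(
    marker: str,
    genotypes: GenotypeMatrix,
    phenos: PhenotypeTable,
    alpha: float = 0.05,
    m_tests: int = 1,
    resistant_allele: str = "B",
) -> AllelicEffect:
    """Genotype-class stratification with nonparametric tests at one marker.

    ``m_tests`` is the Bonferroni multiplier for the Kruskal-Wallis
    trait-level confirmations (typically number of peak markers x number of
    phenotypes); pairwise contrasts used for classification are compared to
    ``alpha`` unadjusted.
    """
    if marker not in genotypes.markers:
        raise KeyError(f"marker {marker!r} not genotyped")
    g = genotypes.table[marker]
    classes = {
        c: phenos.table.loc[g.index[g == c].intersection(phenos.table.index)]
        for c in GENOTYPE_CODES
    }
    classes = {c: t for c, t in classes.items() if len(t) > 0}
    if len(classes) < 2:
        raise ValueError("need >= 2 non-empty genotype classes")
    if len(classes) < 3:
        logger.warning(
            "empty genotype class at %s: collapsing to two-class testing",
            marker,
        )

    class_n = {c: int(len(t)) for c, t in classes.items()}
    class_inc = {c: float(t["INC"].mean()) for c, t in classes.items()}

    rows = []
    kw_p: dict[str, float] = {}
    pairwise: dict[str, dict[tuple[str, str], float]] = {}
    classification: dict[str, str] = {}
    transgressive: dict[str, bool] = {}

    for trait in ALL_TRAITS:
        if trait == "INC":
            locs = dict(class_inc)
            pw = {}
            for c1, c2 in itertools.combinations(sorted(classes), 2):
                t1, t2 = classes[c1], classes[c2]
                tab = [
                    [int(t1["INC"].sum()), int(len(t1) - t1["INC"].sum())],
                    [int(t2["INC"].sum()), int(len(t2) - t2["INC"].sum())],
                ]
                pw[(c1, c2)] = fisher_exact(tab)
            groups = [classes[c]["INC"].to_numpy(float) for c in sorted(classes)]
            kw_p[trait] = kruskal_wallis(*groups)
        else:
            vals = {
                c: t[trait].to_numpy(float)[np.isfinite(t[trait].to_numpy(float))]
                for c, t in classes.items()
            }
            vals = {c: v for c, v in vals.items() if v.size > 0}
            if len(vals) < 2:
                kw_p[trait] = 1.0
                pairwise[trait] = {}
                classification[trait] = "none"
                transgressive[trait] = False
                continue
            locs = {c: float(np.mean(v)) for c, v in vals.items()}
            pw = {}
            for c1, c2 in itertools.combinations(sorted(vals), 2):
                pw[(c1, c2)] = mann_whitney(vals[c1], vals[c2])
            kw_p[trait] = kruskal_wallis(*[vals[c] for c in sorted(vals)])
            for c, v in vals.items():
                rows.append(
                    (trait, c, float(np.mean(v)), float(np.std(v, ddof=1))
                     if v.size > 1 else 0.0, float(np.median(v)))
                )
        pairwise[trait] = pw
        classification[trait] = _classify(locs, pw, alpha)
        sev = {c: _SEVERITY_SIGN[trait] * v for c, v in locs.items()}
        # resistant-strain homozygote (BB when B is resistant) more severe
        # than the opposite homozygote => transgressive
        res_hom = resistant_allele * 2
        alt_hom = ("A" if resistant_allele == "B" else "B") * 2
        transgressive[trait] = (
            res_hom in sev and alt_hom in sev and sev[res_hom] > sev[alt_hom]
        )

    summaries = pd.DataFrame(
        rows, columns=["trait", "class", "mean", "sd", "median"]
    ).set_index(["trait", "class"])

    return AllelicEffect(
        marker=marker,
        class_n=class_n,
        class_incidence=class_inc,
        summaries=summaries,
        kw_p=kw_p,
        kw_p_adj={t: bonferroni(p, m_tests) for t, p in kw_p.items()},
        pairwise_p=pairwise,
        classification=classification,
        transgressive=transgressive,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# genotype-matched congenic prediction
# ---------------------------------------------------------------------------


def predict_congenic(
    genotypes: GenotypeMatrix,
    phenos: PhenotypeTable,
    locus_a: str,
    locus_b: str,
    combos: Sequence[tuple[str, str]] = (("AA", "AA"), ("BB", "BB"), ("AB", "AB")),
    reference: tuple[str, str] = ("AA", "AA"),
) -> pd.DataFrame:
    """Expected congenic phenotypes from genotype-matched AIL animals.

    Selects cohort members matching each (locus_a, locus_b) genotype pair
    and summarizes their phenotypes; each combo is compared with the
    reference combo (the all-DA background) by Fisher's exact test for
    incidence and Mann-Whitney for the quantitative traits. Empty combos
    are reported with n = 0 and no tests.
    """
    if locus_a == locus_b:
        raise ValueError("the two loci must be distinct markers")
    for m in (locus_a, locus_b):
        if m not in genotypes.markers:
            raise KeyError(f"marker {m!r} not genotyped")
    ga = genotypes.table[locus_a]
    gb = genotypes.table[locus_b]

    def select(combo):
        ids = ga.index[(ga == combo[0]) & (gb == combo[1])]
        return phenos.table.loc[ids.intersection(phenos.table.index)]

    ref = select(reference)
    rows = []
    for combo in combos:
        sub = select(combo)
        row: dict[str, object] = {
            "genotype_a": combo[0],
            "genotype_b": combo[1],
            "n": len(sub),
        }
        if len(sub) == 0:
            rows.append(row)
            continue
        row["INC"] = float(sub["INC"].mean())
        for trait in QUANTITATIVE_TRAITS:
            v = sub[trait].to_numpy(float)
            row[trait] = float(np.nanmean(v)) if np.isfinite(v).any() else np.nan
        if combo != reference and len(ref) > 0:
            tab = [
                [int(ref["INC"].sum()), int(len(ref) - ref["INC"].sum())],
                [int(sub["INC"].sum()), int(len(sub) - sub["INC"].sum())],
            ]
            row["p_INC"] = fisher_exact(tab)
            for trait in QUANTITATIVE_TRAITS:
                a = ref[trait].to_numpy(float)
                b = sub[trait].to_numpy(float)
                a, b = a[np.isfinite(a)], b[np.isfinite(b)]
                row[f"p_{trait}"] = (
                    mann_whitney(a, b) if a.size and b.size else np.nan
                )
        rows.append(row)
    return pd.DataFrame(rows)
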