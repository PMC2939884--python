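import numpy as np
import pandas as pd
import pytest

from ailqtl import (
    GeneticMap,
    GenotypeMatrix,
    PhenotypeTable,
    conditional_probabilities,
    make_eae23_fixture,
    make_eae23_map,
)


@pytest.fixture(scope="session")
def eae23_map():
    return make_eae23_map()


@pytest.fixture(scope="session")
def eae23_fixture():
    """Seed-1 desk-scale AIL cohort (pedigree, genotypes, phenotypes)."""
    return make_eae23_fixture(seed=1)


@pytest.fixture(scope="session")
def eae23_probs(eae23_fixture, eae23_map):
    _, geno, _ = eae23_fixture
    return conditional_probabilities(geno, eae23_map, expansion=5.0)


def single_marker_tables(genotype_classes, n_per_class, inc_per_class,
                         marker="Mx", rng=None):
    """Toy one-marker cohort with prescribed per-class incidence.

    ``genotype_classes``: e.g. ("AA", "AB", "BB"); ``inc_per_class``: affected
    counts aligned with ``n_per_class``. Quantitative traits are filled
    consistently with the INC invariant (zero DUR/CUM and undefined ONS for
    unaffected animals).
    """
    rng = rng or np.random.default_rng(0)
    rows_g, rows_p, ids = [], [], []
    k = 0
    for cls, n, aff in zip(genotype_classes, n_per_class, inc_per_class):
        for i in range(n):
            ids.append(f"r{k}")
            rows_g.append(cls)
            inc = 1 if i < aff else 0
            rows_p.append(
                {
                    "sex": "F",
                    "family": f"fam{k % 8}",
                    "INC": inc,
                    "ONS": float(rng.integers(12, 30)) if inc else np.nan,
                    "MAX": float(rng.uniform(0.5, 3.5)) if inc else 0.0,
                    "DUR": float(rng.integers(2, 20)) if inc else 0.0,
                    "CUM": float(rng.uniform(2, 40)) if inc else 0.0,
                    "WL": float(rng.uniform(0, 12)),
                }
            )
            k += 1
    geno = GenotypeMatrix(
        pd.DataFrame({marker: rows_g}, index=pd.Index(ids, name="id"))
    )
    phenos = PhenotypeTable(pd.DataFrame(rows_p, index=pd.Index(ids, name="id")))
    return geno, phenos


def single_marker_grid(codes, marker="Mx", position=10.0):
    """Fully-typed one-marker probability grid from integer codes 0/1/2."""
    from ailqtl.genoprob import GenoProbGrid

    codes = np.asarray(codes, int)
    probs = np.zeros((codes.size, 1, 3))
    probs[np.arange(codes.size), 0, codes] = 1.0
    return GenoProbGrid(
        ids=tuple(f"r{i}" for i in range(codes.size)),
        positions=np.array([position]),
        probs=probs,
        step=0.0,
        markers=(marker,),
    )
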