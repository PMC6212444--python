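import numpy as np
import pandas as pd
import pytest

from eurodiff.simulate import SimConfig, simulate_cohort, write_cohort
from eurodiff.vcfio import IntervalSet, MaskSet


def small_config(seed: int = 11, **overrides) -> SimConfig:
    """A fast cohort: 5 arms, 4,000 sites, 120 genes, 42 strains."""
    kw = dict(
        seed=seed,
        n_sites=4_000,
        n_genes=120,
        n_te=40,
        n_indels=60,
        n_repeats=10,
        small_intron_site_fraction=0.04,
    )
    kw.update(overrides)
    return SimConfig(**kw)


def masks_for(cohort) -> MaskSet:
    return MaskSet(
        euchromatin=IntervalSet.from_frame(cohort.euchromatin),
        repeats=IntervalSet.from_frame(cohort.repeats),
        indel_zones=IntervalSet.from_frame(cohort.indels, pad=5),
    )


@pytest.fixture(scope="session")
def cohort():
    return simulate_cohort(small_config())


@pytest.fixture(scope="session")
def cohort_dir(cohort, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("cohort")
    paths = write_cohort(cohort, outdir)
    return paths


@pytest.fixture(scope="session")
def masks(cohort):
    return masks_for(cohort)


@pytest.fixture(scope="session")
def filtered(cohort, masks):
    from eurodiff.filters import apply_site_filters

    matrix, log = apply_site_filters(cohort.matrix, masks)
    return matrix, log


@pytest.fixture(scope="session")
def scan(cohort, filtered):
    from eurodiff import fst

    matrix, _ = filtered
    sc = fst.fst_scan(matrix, "pop1", "pop2", inversion=cohort.config.inversion_region)
    return fst.assign_tiers(sc)


@pytest.fixture(scope="session")
def chain_dag(tmp_path_factory):
    """Three-term is_a chain: leaf -> mid -> root, for elim tests."""
    from eurodiff.go import load_obo

    obo = "\n".join(
        [
            "format-version: 1.2",
            "",
            "[Term]",
            "id: GO:0000001",
            "name: root",
            "namespace: biological_process",
            "",
            "[Term]",
            "id: GO:0000002",
            "name: mid",
            "namespace: biological_process",
            "is_a: GO:0000001 ! root",
            "",
            "[Term]",
            "id: GO:0000003",
            "name: leaf",
            "namespace: biological_process",
            "is_a: GO:0000002 ! mid",
            "",
        ]
    )
    p = tmp_path_factory.mktemp("obo") / "chain.obo"
    p.write_text(obo)
    return load_obo(p)


def chain_annotation(n_leaf=8, n_mid_extra=20, n_root_extra=60, n_unannotated=20):
    """Gene sets for the chain DAG; returns (gene2go frame, universe).

    The universe includes unannotated genes so that even the root term is a
    proper subset and its Fisher p is informative.
    """
    leaf = [f"L{i}" for i in range(n_leaf)]
    mid = [f"M{i}" for i in range(n_mid_extra)]
    root = [f"R{i}" for i in range(n_root_extra)]
    unann = [f"U{i}" for i in range(n_unannotated)]
    rows = (
        [{"gene_id": g, "go_id": "GO:0000003"} for g in leaf]
        + [{"gene_id": g, "go_id": "GO:0000002"} for g in mid]
        + [{"gene_id": g, "go_id": "GO:0000001"} for g in root]
    )
    return pd.DataFrame(rows), set(leaf + mid + root + unann)
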