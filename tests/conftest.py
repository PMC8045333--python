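import numpy as np
import pandas as pd
import pytest

from binsplice import (
    ApaSiteSet,
    SimConfig,
    build_bins,
    design_from_conditions,
    diffsplice2,
    diffsplice_classic,
    filter_bins,
    fit_bin_models,
    make_toy_annotation,
    read_annotation,
    simulate_utr_counts,
    tmm_factors,
    voom_weights,
)

BENCHMARK_SEED = 0  # the fixed benchmark: 500 genes, 100 with a UTR change


@pytest.fixture(scope="session")
def toy_files(tmp_path_factory):
    """Toy GTF/BED with every optional construct enabled."""
    d = tmp_path_factory.mktemp("toy")
    gtf, bed = make_toy_annotation(
        overlapping_genes=True, far_apa=True, gene_start_guard=True
    )
    (d / "toy.gtf").write_text(gtf)
    (d / "toy.bed").write_text(bed)
    return d / "toy.gtf", d / "toy.bed"


@pytest.fixture(scope="session")
def toy_annotation(toy_files):
    return read_annotation(toy_files[0])


@pytest.fixture(scope="session")
def toy_bins(toy_files, toy_annotation):
    apa = ApaSiteSet.from_bed(toy_files[1])
    return build_bins(toy_annotation, apa)


def fit_pipeline(counts):
    """Filter/normalize/weight/fit a simulated count matrix."""
    design = design_from_conditions(counts.conditions)
    filtered = filter_bins(counts, design)
    normed = tmm_factors(filtered)
    logexpr, weights = voom_weights(normed, design)
    return fit_bin_models(logexpr, weights, design, normed.bin_info)


@pytest.fixture(scope="session")
def benchmark():
    """The seeded differential-UTR benchmark with both methods' results."""
    counts, truth = simulate_utr_counts(SimConfig(seed=BENCHMARK_SEED))
    fits = fit_pipeline(counts)
    return {
        "counts": counts,
        "truth": truth,
        "fits": fits,
        "ds1": diffsplice_classic(fits),
        "ds2": diffsplice2(fits),
    }


@pytest.fixture(scope="session")
def null_results():
    """Seeded null counts (no usage change, no DE) tested with both methods."""
    counts, _ = simulate_utr_counts(
        SimConfig(seed=BENCHMARK_SEED + 7, n_genes=300, n_utr_genes=0,
                  n_de_utr_genes=0, n_de_other_genes=0)
    )
    fits = fit_pipeline(counts)
    return {"ds1": diffsplice_classic(fits), "ds2": diffsplice2(fits)}


def random_gene_fits(rng, n_genes=200, max_bins=6):
    """Random per-bin fit inputs grouped by gene, for oracle checks."""
    rows = []
    for g in range(n_genes):
        n = int(rng.integers(2, max_bins + 1))
        for k in range(n):
            rows.append(
                (
                    f"g{g}:{k + 1}",
                    f"g{g}",
                    rng.normal(0, 2),  # beta
                    float(rng.uniform(0.1, 2.0)),  # u
                    float(rng.uniform(0.2, 3.0)),  # sigma2
                    4.0,  # df
                )
            )
    df = pd.DataFrame(
        rows, columns=["bin_id", "gene", "coef", "u", "sigma2", "df"]
    ).set_index("bin_id")
    df["amean"] = 5.0
    return df


def make_design(n_per_group=3):
    cond = pd.Series(
        ["a"] * n_per_group + ["b"] * n_per_group,
        index=[f"s{i}" for i in range(2 * n_per_group)],
    )
    return design_from_conditions(cond)
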