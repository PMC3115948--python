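import numpy as np
import pytest

from flankfold import (
    SyntheticConfig,
    make_genome,
    simulate_ests,
    simulate_fragments,
    truth_annotations,
    truth_predictions,
)


@pytest.fixture(scope="session")
def default_sim():
    """Default synthetic study: 50 true loci, 5000 decoys, background ESTs."""
    cfg = SyntheticConfig(rng_seed=0)
    sequences, truth = make_genome(cfg)
    ests, est_counts = simulate_ests(truth, cfg)
    frags = simulate_fragments(truth, cfg, est_counts)
    return {
        "cfg": cfg,
        "sequences": sequences,
        "truth": truth,
        "ests": ests,
        "est_counts": est_counts,
        "fragments": frags,
        "annotations": truth_annotations(truth),
        "predictions": truth_predictions(truth),
        "chrom_sizes": cfg.chrom_sizes(),
    }


@pytest.fixture(scope="session")
def small_sim():
    """Small synthetic study for tests that re-run pipeline stages many times."""
    cfg = SyntheticConfig(rng_seed=1, n_true_loci=30, n_decoy_loci=200)
    _, truth = make_genome(cfg)
    ests, est_counts = simulate_ests(truth, cfg)
    return {
        "cfg": cfg,
        "truth": truth,
        "ests": ests,
        "est_counts": est_counts,
        "annotations": truth_annotations(truth),
        "predictions": truth_predictions(truth),
        "chrom_sizes": cfg.chrom_sizes(),
    }


def random_simple_hairpin(rng: np.random.Generator) -> str:
    """Random unbranched dot-bracket: tails, bulged arms, terminal loop.

    The left arm starts and ends with '(' and the right arm starts and ends
    with ')', with random bulges/internal loops between pairs, so the span
    boundaries and the terminal loop are well defined by construction.
    """
    five_tail = int(rng.integers(0, 6))
    three_tail = int(rng.integers(0, 6))
    loop = int(rng.integers(1, 9))
    n_pairs = int(rng.integers(1, 25))
    left_parts: list[str] = []
    right_parts: list[str] = []
    for i in range(n_pairs):
        left_parts.append("(")
        right_parts.append(")")
        if i < n_pairs - 1:
            left_parts.append("." * int(rng.integers(0, 3)))
            right_parts.append("." * int(rng.integers(0, 3)))
    return (
        "." * five_tail
        + "".join(left_parts)
        + "." * loop
        + "".join(right_parts)
        + "." * three_tail
    )
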