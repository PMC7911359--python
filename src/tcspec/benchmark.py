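"""End-to-end recovery benchmark on planted toy worlds.

Runs the full pipeline — sample a toy world, fit cognate and scrambled
Potts models by mean-field DCA, rank inter-domain couplings by direct
information, score the family representatives, classify selection — and
measures how well the planted ground truth is recovered:

* *interface recovery*: fraction of planted interface column pairs found
  among the top-k inter-domain DI pairs (k = number planted);
* *pooled sensitivity*: fraction of cognate family pairs detected by
  positive and/or negative selection across seeds.

Used both by the acceptance checks and as a scriptable sanity check that
the whole chain is wired correctly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment_io import concatenate_pairs, encode_alignment, scramble_pairs
from .dca import compute_weights, count_frequencies, direct_information, fit_mfdca
from .scoring import classify_selection, specificity_matrix, validation_metrics
from .synthetic import family_representatives, make_toy_world


@dataclass
class BenchmarkResult:
    """Pooled recovery metrics over all benchmark seeds."""

    interface_recovery: float
    sensitivity: float
    n_seeds: int
    n_families: int
    per_seed_recovery: list = field(default_factory=list)
    per_seed_sensitivity: list = field(default_factory=list)


def run_world(
    world,
    identity_threshold: float = 0.8,
    scramble_rounds: int = 5,
    seed: int = 0,
):
    """Fit models on one toy world and score its family representatives.

    Returns ``(recovery_fraction, calls, matrix, di)``. The scrambled null
    uses ``scramble_rounds`` rounds (5 by default here: a scaled-down
    population adequate for the small toy proteomes; organism-scale runs
    default to 25 rounds in the pipeline).
    """
    paired = concatenate_pairs(world.hk_alignment, world.rr_alignment, world.pair_table)
    enc = encode_alignment(paired.alignment)
    weights, _ = compute_weights(enc, identity_threshold)
    freqs = count_frequencies(enc, weights)
    cognate = fit_mfdca(freqs, provenance="cognate")

    scrambled = scramble_pairs(
        world.hk_alignment, world.rr_alignment, rounds=scramble_rounds, seed=seed
    )
    enc0 = encode_alignment(scrambled.alignment)
    weights0, _ = compute_weights(enc0, identity_threshold)
    freqs0 = count_frequencies(enc0, weights0)
    null = fit_mfdca(freqs0, provenance="scrambled")

    di = direct_information(cognate, freqs)
    mask = world.planted_mask
    k = len(mask.pairs)
    inter = [(i, j) for i, j, _ in di.ranking() if i < mask.l_hk <= j][:k]
    recovery = sum(1 for p in inter if p in mask.pairs) / k

    hk_reps, rr_reps, cmap = family_representatives(world)
    matrix = specificity_matrix(cognate, null, mask, hk_reps, rr_reps)
    calls, _ = classify_selection(matrix, cmap)
    return recovery, calls, matrix, di


def run_recovery_benchmark(
    n_seeds: int = 10,
    master_seed: int = 0,
    n_hk_families: int = 5,
    M_per_family: int = 500,
    coupling_strength: float = 3.0,
    scramble_rounds: int = 5,
    **world_kwargs,
) -> BenchmarkResult:
    """Pooled planted-recovery benchmark over ``n_seeds`` independent worlds."""
    seed_rng = np.random.default_rng(master_seed)
    world_seeds = seed_rng.integers(0, 2**31, size=n_seeds)
    all_calls = []
    per_recovery, per_sens = [], []
    for ws in world_seeds:
        world = make_toy_world(
            n_hk_families=n_hk_families,
            M_per_family=M_per_family,
            coupling_strength=coupling_strength,
            seed=int(ws),
            **world_kwargs,
        )
        recovery, calls, _, _ = run_world(
            world, scramble_rounds=scramble_rounds, seed=int(ws) % (2**31)
        )
        per_recovery.append(recovery)
        per_sens.append(validation_metrics(calls).sensitivity)
        all_calls.extend(calls)
    pooled = validation_metrics(all_calls)
    return BenchmarkResult(
        interface_recovery=float(np.mean(per_recovery)),
        sensitivity=pooled.sensitivity,
        n_seeds=n_seeds,
        n_families=n_hk_families,
        per_seed_recovery=per_recovery,
        per_seed_sensitivity=per_sens,
    )
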