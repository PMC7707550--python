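"""Shared cohort builders for the acceptance suite."""

from strainwss import (
    evolve_or_replace,
    hash_seed,
    observe_group,
    simulate_reference,
    simulate_strain,
)


def make_pair_cohort(
    n_related,
    n_unrelated,
    seed,
    genome_length=20_000,
    snv_density=0.01,
    drift=0.02,
    mean_depth=20,
    dropout=0.05,
    call_error=0.005,
):
    """n_related drifted pairs + n_unrelated replaced pairs on one reference,
    observed with shared allele indexing.  Returns (reference, profiles,
    truth) with profiles[2i], profiles[2i+1] forming pair i."""
    reference = simulate_reference(genome_length, seed)
    named, truth = [], []
    for i in range(n_related + n_unrelated):
        replacement = 0.0 if i < n_related else 1.0
        hap_a = simulate_strain(reference, snv_density, seed=hash_seed(seed, i, 0))
        hap_b, label = evolve_or_replace(
            hap_a, drift, replacement, reference, snv_density,
            seed=hash_seed(seed, i, 1),
        )
        named.append((f"P{i:03d}_a", f"P{i:03d}", "t0", hap_a))
        named.append((f"P{i:03d}_b", f"P{i:03d}", "t1", hap_b))
        truth.append(label)
    profiles = observe_group(
        named, reference, mean_depth, dropout, call_error,
        seed=hash_seed(seed, 999_983),
    )
    return reference, profiles, truth
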