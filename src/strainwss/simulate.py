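"""Synthetic cohorts with ground-truth strain relatedness.

Per species: a random reference, per-individual SNV haplotypes at a stated
density, longitudinal persistence with small per-site drift vs independent
replacement strains, Poisson depth with dropout, and genotype-call error —
written out as FASTA + multi-sample VCF + per-sample depth TSVs so the real
data path is exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ParameterError
from .profile_io import DepthTrack, ReferenceGenome, SampleProfile, VariantCall

BASES = "ACGT"

#: fixed offsets mixed into the seed so each stochastic stage gets an
#: independent stream
_STAGE_STRAIN = 1
_STAGE_EVOLVE = 2
_STAGE_OBSERVE = 3
_STAGE_REFERENCE = 4


@dataclass
class SimulationConfig:
    genome_length: int = 20_000
    snv_density: float = 0.01
    drift: float = 0.02
    replacement_prob: float = 0.0
    mean_depth: float = 20.0
    dropout: float = 0.05
    call_error: float = 0.005
    n_individuals: int = 8
    n_timepoints: int = 2
    seed: int = 0
    species_id: str = "species_1"
    sequence_id: str = "ref_1"

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise ParameterError("genome_length must be >= 1")
        if self.n_individuals < 1 or self.n_timepoints < 1:
            raise ParameterError("need >= 1 individual and timepoint")
        if self.mean_depth < 0:
            raise ParameterError("mean_depth must be >= 0")
        for name in ("snv_density", "drift", "replacement_prob", "dropout", "call_error"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ParameterError(f"{name}={value} outside [0,1]")


@dataclass(frozen=True)
class TruthRecord:
    individual_id: str
    species_id: str
    timepoint_a: str
    timepoint_b: str
    truth_label: str  # related | unrelated


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    reference: ReferenceGenome
    profiles: list[SampleProfile]
    truth: list[TruthRecord]
    paths: dict[str, Path] = field(default_factory=dict)

    def profiles_by_individual(self) -> dict[str, list[SampleProfile]]:
        out: dict[str, list[SampleProfile]] = {}
        for p in self.profiles:
            out.setdefault(p.individual_id, []).append(p)
        return out


# Haplotype = mapping 1-based position -> alt base (differing from reference).
Haplotype = dict[int, str]


def simulate_reference(
    genome_length: int,
    seed: int,
    species_id: str = "species_1",
    sequence_id: str = "ref_1",
    cutoff: float | None = None,
) -> ReferenceGenome:
    """Uniform-random base sequence, seeded and reproducible."""
    if genome_length < 1:
        raise ParameterError("genome_length must be >= 1")
    rng = np.random.default_rng([seed, _STAGE_REFERENCE])
    seq = "".join(np.array(list(BASES))[rng.integers(0, 4, size=genome_length)])
    return ReferenceGenome(
        species_id=species_id,
        sequence_id=sequence_id,
        length=genome_length,
        cutoff=cutoff,
        sequence=seq,
    )


def _random_other_base(rng: np.random.Generator, exclude: str) -> str:
    choices = [b for b in BASES if b != exclude]
    return choices[rng.integers(0, len(choices))]


def simulate_strain(
    reference: ReferenceGenome, snv_density: float, seed: int
) -> Haplotype:
    """Each site independently polymorphic with probability snv_density; the
    alt base is uniform over the 3 non-reference bases."""
    rng = np.random.default_rng([seed, _STAGE_STRAIN])
    hits = np.nonzero(rng.random(reference.length) < snv_density)[0]
    hap: Haplotype = {}
    for idx in hits:
        pos = int(idx) + 1
        hap[pos] = _random_other_base(rng, reference.sequence[idx])
    return hap


def evolve_or_replace(
    haplotype: Haplotype,
    drift: float,
    replacement_prob: float,
    reference: ReferenceGenome,
    snv_density: float,
    seed: int,
) -> tuple[Haplotype, str]:
    """Next-timepoint strain: with probability ``replacement_prob`` an
    independent fresh strain (unrelated); otherwise a copy whose sites each
    resample to a different state with probability ``drift`` (related).

    Resampling picks uniformly among the 3 states other than the current one
    (the reference base and the two remaining alts), so a resampled site
    always changes state and may revert to reference.
    """
    rng = np.random.default_rng([seed, _STAGE_EVOLVE])
    if rng.random() < replacement_prob:
        return simulate_strain(reference, snv_density, seed), "unrelated"
    evolved: Haplotype = {}
    for pos in sorted(haplotype):
        alt = haplotype[pos]
        if rng.random() < drift:
            ref_base = reference.sequence[pos - 1]
            new_state = _random_other_base(rng, alt)
            if new_state != ref_base:
                evolved[pos] = new_state
            # new_state == ref_base: site reverts to reference (dropped)
        else:
            evolved[pos] = alt
    return evolved, "related"


def _observe_raw(
    haplotype: Haplotype,
    reference: ReferenceGenome,
    mean_depth: float,
    dropout: float,
    call_error: float,
    seed: int,
) -> tuple[Haplotype, np.ndarray]:
    """Observed alt bases + per-base depth for one sample.

    Depth is Poisson(mean_depth) with an independent dropout mask; a site's
    call is emitted only where depth >= 1; with probability ``call_error``
    the observed state is perturbed to one of the 3 other states (possibly
    reference, in which case no call is emitted).
    """
    rng = np.random.default_rng([seed, _STAGE_OBSERVE])
    depth = rng.poisson(mean_depth, size=reference.length)
    if dropout > 0:
        depth[rng.random(reference.length) < dropout] = 0
    observed: Haplotype = {}
    for pos in sorted(haplotype):
        if depth[pos - 1] < 1:
            continue
        state = haplotype[pos]
        if call_error > 0 and rng.random() < call_error:
            state = _random_other_base(rng, state)
        if state != reference.sequence[pos - 1]:
            observed[pos] = state
    return observed, depth


def _site_allele_index(
    observations: Sequence[Haplotype],
) -> dict[int, dict[str, int]]:
    """Global allele indexing: per polymorphic site, sorted distinct alt
    bases across all samples get indices 1, 2, ..."""
    alts_by_pos: dict[int, set[str]] = {}
    for obs in observations:
        for pos, alt in obs.items():
            alts_by_pos.setdefault(pos, set()).add(alt)
    return {
        pos: {alt: i + 1 for i, alt in enumerate(sorted(alts))}
        for pos, alts in alts_by_pos.items()
    }


def _profile_from_observation(
    observed: Haplotype,
    depth: np.ndarray,
    reference: ReferenceGenome,
    allele_index: Mapping[int, Mapping[str, int]],
    sample_id: str,
    individual_id: str,
    timepoint_label: str,
) -> SampleProfile:
    calls = {
        pos: VariantCall(
            position=pos,
            ref_allele=reference.sequence[pos - 1],
            alt_allele=alt,
            genotype_state=allele_index[pos][alt],
            depth_at_site=int(depth[pos - 1]),
        )
        for pos, alt in sorted(observed.items())
    }
    return SampleProfile(
        sample_id=sample_id,
        individual_id=individual_id,
        timepoint_label=timepoint_label,
        reference=reference,
        calls=calls,
        depth=DepthTrack(reference=reference, depth=depth),
    )


def observe(
    haplotype: Haplotype,
    reference: ReferenceGenome,
    mean_depth: float,
    dropout: float,
    call_error: float,
    seed: int,
    sample_id: str = "sample",
    individual_id: str = "individual",
    timepoint_label: str = "t0",
) -> SampleProfile:
    """Observe a single strain as a SampleProfile (single-sample allele
    indexing; cohort-level VCF indexing is handled by simulate_cohort)."""
    observed, depth = _observe_raw(
        haplotype, reference, mean_depth, dropout, call_error, seed
    )
    allele_index = _site_allele_index([observed])
    return _profile_from_observation(
        observed, depth, reference, allele_index,
        sample_id, individual_id, timepoint_label,
    )


def observe_group(
    named_haplotypes: Sequence[tuple[str, str, str, Haplotype]],
    reference: ReferenceGenome,
    mean_depth: float,
    dropout: float,
    call_error: float,
    seed: int,
) -> list[SampleProfile]:
    """Observe several strains with SHARED allele indexing, as a multi-sample
    VCF would assign it — required whenever the resulting profiles are
    compared with each other.

    ``named_haplotypes`` is a sequence of
    (sample_id, individual_id, timepoint_label, haplotype); the per-sample
    observation seed is derived from ``seed`` and the sequence index.
    """
    raw = [
        _observe_raw(
            hap, reference, mean_depth, dropout, call_error,
            seed=hash_seed(seed, idx, _STAGE_OBSERVE),
        )
        for idx, (_, _, _, hap) in enumerate(named_haplotypes)
    ]
    allele_index = _site_allele_index([obs for obs, _ in raw])
    return [
        _profile_from_observation(
            obs, depth, reference, allele_index, sample_id, individual_id, timepoint
        )
        for (sample_id, individual_id, timepoint, _), (obs, depth) in zip(
            named_haplotypes, raw
        )
    ]


def _write_fasta(reference: ReferenceGenome, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{reference.sequence_id}\n")
        seq = reference.sequence
        for i in range(0, len(seq), 80):
            fh.write(seq[i : i + 80] + "\n")


def _write_species_table(reference: ReferenceGenome, path: Path) -> None:
    cutoff = "NA" if reference.cutoff is None else f"{reference.cutoff:.6g}"
    with open(path, "w") as fh:
        fh.write("species_id\tsequence_id\tcutoff\n")
        fh.write(f"{reference.species_id}\t{reference.sequence_id}\t{cutoff}\n")


def _write_depth_tsv(profile: SampleProfile, path: Path) -> None:
    depth = profile.depth.depth
    with open(path, "w") as fh:
        for idx in np.nonzero(depth > 0)[0]:
            fh.write(f"{profile.reference.sequence_id}\t{idx + 1}\t{depth[idx]}\n")


def write_vcf(
    profiles: Sequence[SampleProfile], reference: ReferenceGenome, path: Path
) -> None:
    """Multi-sample VCF 4.2 with homozygous diploid-style genotypes; samples
    without a call are 0/0 where covered and ./. where depth is zero."""
    sample_ids = [p.sample_id for p in profiles]
    positions = sorted({pos for p in profiles for pos in p.calls})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            f"##contig=<ID={reference.sequence_id},length={reference.length}>\n"
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for pos in positions:
            alts: dict[str, int] = {}
            for p in profiles:
                call = p.calls.get(pos)
                if call is not None:
                    alts[call.alt_allele] = call.genotype_state
            alt_field = ",".join(
                alt for alt, _ in sorted(alts.items(), key=lambda kv: kv[1])
            )
            fields = [
                reference.sequence_id,
                str(pos),
                ".",
                reference.sequence[pos - 1],
                alt_field,
                ".",
                "PASS",
                ".",
                "GT:DP",
            ]
            for p in profiles:
                site_depth = int(p.depth.depth[pos - 1])
                call = p.calls.get(pos)
                if call is not None:
                    gt = f"{call.genotype_state}/{call.genotype_state}"
                elif site_depth > 0:
                    gt = "0/0"
                else:
                    gt = "./."
                fields.append(f"{gt}:{site_depth}")
            fh.write("\t".join(fields) + "\n")


def _write_truth(truth: Sequence[TruthRecord], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("individual_id\tspecies_id\ttimepoint_a\ttimepoint_b\ttruth_label\n")
        for rec in truth:
            fh.write(
                f"{rec.individual_id}\t{rec.species_id}\t{rec.timepoint_a}\t"
                f"{rec.timepoint_b}\t{rec.truth_label}\n"
            )


def _write_sample_map(profiles: Sequence[SampleProfile], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tindividual_id\ttimepoint_label\n")
        for p in profiles:
            fh.write(f"{p.sample_id}\t{p.individual_id}\t{p.timepoint_label}\n")


def simulate_cohort(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SyntheticCohort:
    """Simulate n_individuals x n_timepoints profiles for one species.

    Each individual starts from an independent strain; successive timepoints
    either drift (related) or are replaced (unrelated) per
    :func:`evolve_or_replace`.  Truth labels cover every within-individual
    timepoint pair: related iff no replacement occurred between them.
    When ``out_dir`` is given the cohort is also written as FASTA,
    species table, multi-sample VCF, per-sample depth TSVs, a sample map
    and a truth table.
    """
    reference = simulate_reference(
        config.genome_length, config.seed, config.species_id, config.sequence_id
    )
    observations: list[Haplotype] = []
    depths: list[np.ndarray] = []
    meta: list[tuple[str, str, str]] = []  # (sample_id, individual_id, timepoint)
    truth: list[TruthRecord] = []

    for ind_idx in range(config.n_individuals):
        individual_id = f"I{ind_idx + 1:02d}"
        hap = simulate_strain(
            reference, config.snv_density, seed=hash_seed(config.seed, ind_idx, 0)
        )
        lineages = [0]
        haps = [hap]
        for t in range(1, config.n_timepoints):
            hap, label = evolve_or_replace(
                haps[-1],
                config.drift,
                config.replacement_prob,
                reference,
                config.snv_density,
                seed=hash_seed(config.seed, ind_idx, t),
            )
            haps.append(hap)
            lineages.append(lineages[-1] + (1 if label == "unrelated" else 0))
        for t, hap_t in enumerate(haps):
            sample_id = f"{individual_id}_t{t}"
            observed, depth = _observe_raw(
                hap_t,
                reference,
                config.mean_depth,
                config.dropout,
                config.call_error,
                seed=hash_seed(config.seed, ind_idx, t, 1),
            )
            observations.append(observed)
            depths.append(depth)
            meta.append((sample_id, individual_id, f"t{t}"))
        for ta in range(config.n_timepoints):
            for tb in range(ta + 1, config.n_timepoints):
                truth.append(
                    TruthRecord(
                        individual_id=individual_id,
                        species_id=config.species_id,
                        timepoint_a=f"t{ta}",
                        timepoint_b=f"t{tb}",
                        truth_label=(
                            "related" if lineages[ta] == lineages[tb] else "unrelated"
                        ),
                    )
                )

    allele_index = _site_allele_index(observations)
    profiles = [
        _profile_from_observation(
            obs, depth, reference, allele_index, sample_id, individual_id, timepoint
        )
        for obs, depth, (sample_id, individual_id, timepoint) in zip(
            observations, depths, meta
        )
    ]

    cohort = SyntheticCohort(
        config=config, reference=reference, profiles=profiles, truth=truth
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        depth_dir = out / "depth"
        depth_dir.mkdir(exist_ok=True)
        paths = {
            "fasta": out / "reference.fasta",
            "species_table": out / "species_table.tsv",
            "vcf": out / "variants.vcf",
            "truth": out / "truth.tsv",
            "sample_map": out / "sample_map.tsv",
            "depth_dir": depth_dir,
        }
        _write_fasta(reference, paths["fasta"])
        _write_species_table(reference, paths["species_table"])
        write_vcf(profiles, reference, paths["vcf"])
        _write_truth(truth, paths["truth"])
        _write_sample_map(profiles, paths["sample_map"])
        for p in profiles:
            _write_depth_tsv(p, depth_dir / f"{p.sample_id}.depth.tsv")
        cohort.paths = paths
    return cohort


def hash_seed(*parts: int) -> int:
    """Deterministic seed derivation by mixing integer parts (no randomness
    of its own; stable across runs and platforms)."""
    state = 0x9E3779B97F4A7C15
    for part in parts:
        state ^= (part + 0x9E3779B97F4A7C15 + (state << 6) + (state >> 2)) % 2**64
        state %= 2**64
    return state % 2**63
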