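"""Read references, depth tracks and multi-sample variant calls into sample
profiles; apply sample-level QC filters; merge pooled samples.

Coordinates are 1-based inclusive in all file I/O (VCF / depth-TSV
convention) and 0-based half-open internally for window arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import (
    CatalogError,
    CoordinateError,
    FormatError,
    InputError,
    MergeError,
)

logger = logging.getLogger(__name__)

#: sentinel strings accepted as "no cutoff" in a species table
NA_SENTINELS = {"NA", "CO:NA", "", "nan", "NaN", "None"}

DEFAULT_BREADTH_MIN = 0.30
DEFAULT_DEPTH_MIN = 3.5


@dataclass(frozen=True)
class ReferenceGenome:
    """One species reference sequence.

    ``cutoff`` is the per-species related/unrelated decision threshold, or
    ``None`` when the species has no assigned cutoff ("CO:NA").  ``sequence``
    is retained when the genome was read from FASTA (needed to emit VCF REF
    columns) but is not required for scoring.
    """

    species_id: str
    sequence_id: str
    length: int
    cutoff: float | None = None
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise CatalogError(f"reference {self.sequence_id!r}: length must be >= 1")
        if self.cutoff is not None and not (0.0 < self.cutoff < 1.0):
            raise CatalogError(
                f"reference {self.sequence_id!r}: cutoff {self.cutoff} not in (0,1)"
            )
        if self.sequence is not None and len(self.sequence) != self.length:
            raise CatalogError(
                f"reference {self.sequence_id!r}: sequence length != declared length"
            )


@dataclass
class DepthTrack:
    """Dense per-base read depth over a reference (index 0 = position 1)."""

    reference: ReferenceGenome
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if self.depth.shape != (self.reference.length,):
            raise FormatError(
                f"depth track has {self.depth.shape[0]} entries, "
                f"reference length is {self.reference.length}"
            )
        if np.any(self.depth < 0):
            raise FormatError("negative depth value")


@dataclass(frozen=True, order=True)
class VariantCall:
    """One sample's non-reference state at one position.

    ``genotype_state`` is the allele index in the multi-sample VCF record:
    0 = reference, k >= 1 = k-th alternate allele.
    """

    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    genotype_state: int
    depth_at_site: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise CoordinateError(f"position {self.position} < 1")
        if self.alt_allele == self.ref_allele:
            raise FormatError("alt allele equals ref allele")
        if self.genotype_state < 0:
            raise FormatError("genotype_state must be >= 0")
        if self.depth_at_site < 0:
            raise FormatError("negative depth_at_site")


@dataclass
class SampleProfile:
    """One sample's evidence against one species reference."""

    sample_id: str
    individual_id: str
    timepoint_label: str
    reference: ReferenceGenome
    calls: dict[int, VariantCall]  # keyed by 1-based position
    depth: DepthTrack
    breadth: float = field(init=False)
    mean_depth: float = field(init=False)

    def __post_init__(self) -> None:
        for pos, call in self.calls.items():
            if pos != call.position:
                raise FormatError("calls dict key disagrees with call position")
            if call.position > self.reference.length:
                raise CoordinateError(
                    f"call at {call.position} beyond reference length "
                    f"{self.reference.length}"
                )
        self.recompute_metrics()
        self._pos_cache: np.ndarray | None = None
        self._state_cache: np.ndarray | None = None

    def recompute_metrics(self) -> None:
        d = self.depth.depth
        self.breadth = float(np.count_nonzero(d >= 1)) / self.reference.length
        self.mean_depth = float(d.sum()) / self.reference.length

    # Sorted position / state arrays, cached for fast pairwise comparison.
    @property
    def call_positions(self) -> np.ndarray:
        if self._pos_cache is None:
            self._pos_cache = np.fromiter(
                sorted(self.calls), dtype=np.int64, count=len(self.calls)
            )
        return self._pos_cache

    @property
    def call_states(self) -> np.ndarray:
        if self._state_cache is None:
            self._state_cache = np.fromiter(
                (self.calls[p].genotype_state for p in self.call_positions),
                dtype=np.int64,
                count=len(self.calls),
            )
        return self._state_cache


@dataclass
class QCDecision:
    sample_id: str
    passed: bool
    reasons: list[dict]

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must be true iff reasons is empty")


def _parse_cutoff(value) -> float | None:
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    text = str(value).strip()
    if text in NA_SENTINELS:
        return None
    try:
        cutoff = float(text)
    except ValueError as exc:
        raise FormatError(f"unparseable cutoff {value!r}") from exc
    return cutoff


def read_reference_catalog(
    fasta_path: str | Path, species_table_path: str | Path
) -> list[ReferenceGenome]:
    """Read a FASTA + species table into a reference catalog.

    The species table is a TSV with header ``species_id  sequence_id  cutoff``;
    the cutoff column is optional and accepts the NA sentinels.
    """
    records = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in records:
            raise CatalogError(f"duplicate FASTA record {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise InputError(f"empty FASTA: {fasta_path}")

    table = pd.read_csv(species_table_path, sep="\t", dtype=str)
    required = {"species_id", "sequence_id"}
    if not required.issubset(table.columns):
        raise CatalogError(
            f"species table must have columns {sorted(required)}, "
            f"got {list(table.columns)}"
        )
    if table["sequence_id"].duplicated().any():
        dups = table.loc[table["sequence_id"].duplicated(), "sequence_id"].tolist()
        raise CatalogError(f"duplicate sequence_id rows: {dups}")
    if table["species_id"].duplicated().any():
        dups = table.loc[table["species_id"].duplicated(), "species_id"].tolist()
        raise CatalogError(f"duplicate species_id rows: {dups}")

    catalog = []
    for row in table.itertuples(index=False):
        seq = records.get(row.sequence_id)
        if seq is None:
            raise CatalogError(f"sequence_id {row.sequence_id!r} not in FASTA")
        cutoff = _parse_cutoff(getattr(row, "cutoff", None))
        catalog.append(
            ReferenceGenome(
                species_id=row.species_id,
                sequence_id=row.sequence_id,
                length=len(seq),
                cutoff=cutoff,
                sequence=seq,
            )
        )
    missing = set(records) - set(table["sequence_id"])
    if missing:
        raise CatalogError(f"FASTA records absent from species table: {sorted(missing)}")
    return catalog


def read_depth(depth_tsv_path: str | Path, reference: ReferenceGenome) -> DepthTrack:
    """Read a samtools-depth style TSV (chrom TAB 1-based-pos TAB depth).

    Rows for other chromosomes are ignored; unlisted positions are depth 0.
    """
    depth = np.zeros(reference.length, dtype=np.int64)
    try:
        table = pd.read_csv(
            depth_tsv_path,
            sep="\t",
            header=None,
            names=["chrom", "pos", "depth"],
            dtype={"chrom": str, "pos": np.int64, "depth": np.int64},
        )
    except pd.errors.EmptyDataError:
        return DepthTrack(reference=reference, depth=depth)
    except ValueError as exc:
        raise FormatError(f"malformed depth TSV {depth_tsv_path}: {exc}") from exc

    table = table[table["chrom"] == reference.sequence_id]
    if len(table) == 0:
        return DepthTrack(reference=reference, depth=depth)
    pos = table["pos"].to_numpy()
    val = table["depth"].to_numpy()
    if np.any(val < 0):
        raise FormatError(f"negative depth in {depth_tsv_path}")
    if np.any(pos < 1) or np.any(pos > reference.length):
        bad = pos[(pos < 1) | (pos > reference.length)][0]
        raise CoordinateError(
            f"depth position {bad} outside 1..{reference.length} "
            f"on {reference.sequence_id}"
        )
    depth[pos - 1] = val
    return DepthTrack(reference=reference, depth=depth)


def _is_snv(ref: str, alts: Sequence[str]) -> bool:
    if len(ref) != 1:
        return False
    return all(len(a) == 1 and a in "ACGTacgt" for a in alts)


def read_variant_profiles(
    vcf_path: str | Path,
    reference: ReferenceGenome,
    sample_depths: Mapping[str, DepthTrack],
    sample_meta: Mapping[str, tuple[str, str]] | None = None,
) -> list[SampleProfile]:
    """Read a multi-sample VCF into one SampleProfile per sample column.

    A record contributes a VariantCall to every sample whose genotype is a
    non-reference allele.  Indel / non-SNV records are skipped with a logged
    count; the analysis is SNV-only.  ``sample_meta`` optionally maps
    sample_id -> (individual_id, timepoint_label); by default the sample is
    its own individual.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    for s in samples:
        if s not in sample_depths:
            raise InputError(f"no depth track supplied for sample {s!r}")

    calls: dict[str, dict[int, VariantCall]] = {s: {} for s in samples}
    skipped_non_snv = 0
    for variant in vcf:
        if variant.CHROM != reference.sequence_id:
            raise InputError(
                f"VCF chrom {variant.CHROM!r} does not match reference "
                f"{reference.sequence_id!r}"
            )
        pos = variant.POS
        if pos < 1 or pos > reference.length:
            raise CoordinateError(
                f"VCF position {pos} outside 1..{reference.length}"
            )
        alts = variant.ALT
        if not _is_snv(variant.REF, alts):
            skipped_non_snv += 1
            continue
        genotypes = variant.genotypes
        for i, s in enumerate(samples):
            allele = genotypes[i][0]
            if allele is None or allele <= 0:
                continue
            depth_at_site = int(sample_depths[s].depth[pos - 1])
            calls[s][pos] = VariantCall(
                position=pos,
                ref_allele=variant.REF,
                alt_allele=alts[allele - 1],
                genotype_state=int(allele),
                depth_at_site=depth_at_site,
            )
    if skipped_non_snv:
        logger.warning(
            "skipped %d non-SNV record(s) in %s", skipped_non_snv, vcf_path
        )

    profiles = []
    for s in samples:
        individual, timepoint = (sample_meta or {}).get(s, (s, ""))
        profiles.append(
            SampleProfile(
                sample_id=s,
                individual_id=individual,
                timepoint_label=timepoint,
                reference=reference,
                calls=calls[s],
                depth=sample_depths[s],
            )
        )
    return profiles


def qc_filter(
    profile: SampleProfile,
    breadth_min: float = DEFAULT_BREADTH_MIN,
    depth_min: float = DEFAULT_DEPTH_MIN,
    depth_over_covered: bool = False,
) -> QCDecision:
    """Sample-level QC: fail iff breadth < breadth_min OR mean depth < depth_min.

    Thresholds are strict (<): boundary values pass.  ``depth_over_covered``
    averages depth over covered positions only instead of the whole genome.
    """
    reasons = []
    if profile.breadth < breadth_min:
        reasons.append(
            {"metric": "coverage", "value": profile.breadth, "threshold": breadth_min}
        )
    if depth_over_covered:
        d = profile.depth.depth
        covered = d[d >= 1]
        mean_depth = float(covered.mean()) if covered.size else 0.0
    else:
        mean_depth = profile.mean_depth
    if mean_depth < depth_min:
        reasons.append(
            {"metric": "depth", "value": mean_depth, "threshold": depth_min}
        )
    return QCDecision(sample_id=profile.sample_id, passed=not reasons, reasons=reasons)


def merge_profiles(
    profiles: Sequence[SampleProfile], sample_id: str | None = None
) -> SampleProfile:
    """Merge pooled samples into a single profile.

    Depth vectors are summed position-wise.  At each variant position the
    merged allele state is the depth-weighted majority across inputs (a
    profile with no call contributes its site depth to the reference state);
    ties go to the state of the input with the larger site depth, remaining
    ties to the lower allele index.
    """
    if not profiles:
        raise MergeError("no profiles to merge")
    ref = profiles[0].reference
    individual = profiles[0].individual_id
    for p in profiles[1:]:
        if p.reference.sequence_id != ref.sequence_id:
            raise MergeError(
                f"cannot merge profiles on different references "
                f"({p.reference.sequence_id!r} vs {ref.sequence_id!r})"
            )
        if p.individual_id != individual:
            raise MergeError("cannot merge profiles from different individuals")

    merged_depth = np.zeros(ref.length, dtype=np.int64)
    for p in profiles:
        merged_depth += p.depth.depth

    positions = sorted({pos for p in profiles for pos in p.calls})
    merged_calls: dict[int, VariantCall] = {}
    for pos in positions:
        weight: dict[int, int] = {}
        best_single: dict[int, int] = {}
        exemplar: dict[int, VariantCall] = {}
        for p in profiles:
            call = p.calls.get(pos)
            site_depth = int(p.depth.depth[pos - 1])
            state = call.genotype_state if call is not None else 0
            weight[state] = weight.get(state, 0) + site_depth
            best_single[state] = max(best_single.get(state, 0), site_depth)
            if call is not None and state not in exemplar:
                exemplar[state] = call
        # majority by summed depth; ties by largest single-input site depth,
        # then by lower allele index
        winner = min(
            weight,
            key=lambda s: (-weight[s], -best_single[s], s),
        )
        if winner >= 1:
            template = exemplar[winner]
            merged_calls[pos] = replace(
                template, depth_at_site=int(merged_depth[pos - 1])
            )

    return SampleProfile(
        sample_id=sample_id or "+".join(p.sample_id for p in profiles),
        individual_id=individual,
        timepoint_label=profiles[0].timepoint_label if len(profiles) == 1 else "merged",
        reference=ref,
        calls=merged_calls,
        depth=DepthTrack(reference=ref, depth=merged_depth),
    )
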