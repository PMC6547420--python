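"""Synthetic MIC genome and deletion-evidence generator.

Emulates the data regime of a multi-strain *Tetrahymena* germline-genome
study without any sequencing data: an AT-rich multi-contig micronuclear
(MIC) reference with planted internal eliminated sequences (IESs), flanking
inverted-repeat (IR) motifs at configurable distances from the deletion
boundaries, junction microhomology, per-strain boundary jitter
(microheterogeneity), intra-strain alternative forms, strain-specific
locus dropout, and — for LIA3-knockout-like strains — inflated boundary
jitter at motif-marked loci only.

Evidence is emitted at the level a structural-variant caller and a
split-read pileup would provide: approximate candidate deletion intervals
and per-position clipped-read count profiles.  Full truth tables are
retained so every downstream stage is testable.

All coordinates are 0-based half-open [A, B).  One global seed drives the
run; per-strain substreams are derived by hashing (seed, strain), so adding
a strain never changes another strain's draws.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._seq import revcomp
from .catalog import IESForm

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigurationError(ValueError):
    """Raised for infeasible or inconsistent simulation configurations."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic MIC/MAC experiment.

    Defaults mirror the biological regime being emulated: ~75% AT genome,
    IESs of a few hundred bp, a hexamer IR planted ~45 bp outside each
    boundary with small positional jitter, wild-type boundary
    microheterogeneity of a few bp, and grossly inflated (±150 bp) jitter
    in mutant strains at motif-marked loci.
    """

    n_contigs: int = 2
    contig_length: int = 200_000
    gc_fraction: float = 0.25
    n_ies: int = 30
    ies_length_range: tuple[int, int] = (250, 600)
    ir_motif: str = "TACCGT"
    ir_distance: int = 45
    ir_jitter: int = 3
    motif_fraction: float = 1.0
    microhomology_length_range: tuple[int, int] = (0, 6)
    strains: tuple[str, ...] = ("CU427", "CU428", "BII")
    boundary_jitter_wt: int = 5
    boundary_jitter_mut: int = 150
    mut_strains: tuple[str, ...] = ()
    dup_fraction: float = 0.01
    skip_fraction: float = 0.02
    clip_support: int = 30
    clip_noise_rate: float = 0.0005
    candidate_displacement: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ConfigurationError("gc_fraction must lie in [0, 1]")
        if not 0.0 <= self.clip_noise_rate <= 1.0:
            raise ConfigurationError("clip_noise_rate must lie in [0, 1]")
        lo, hi = self.ies_length_range
        mh_lo, mh_hi = self.microhomology_length_range
        if mh_lo < 0 or mh_hi < mh_lo:
            raise ConfigurationError("invalid microhomology_length_range")
        if lo < 100 + 2 * mh_hi or hi < lo:
            raise ConfigurationError(
                "ies_length_range min must be ≥ 100 + 2·max microhomology"
            )
        if self.ir_motif != "none" and set(self.ir_motif) - set("ACGT"):
            raise ConfigurationError("ir_motif must be over {A,C,G,T} or 'none'")
        if not set(self.mut_strains) <= set(self.strains):
            raise ConfigurationError("mut_strains must be a subset of strains")
        if self.ir_motif != "none" and self.ir_jitter > self.ir_distance:
            raise ConfigurationError("ir_jitter must not exceed ir_distance")

    @property
    def motif_length(self) -> int:
        return 0 if self.ir_motif == "none" else len(self.ir_motif)

    @property
    def placement_margin(self) -> int:
        """Minimum clearance between IESs and from contig ends.

        Chosen so that 100-bp flank extraction, ±500-bp composition
        profiles and motif planting never truncate or collide.
        """
        return 2 * (self.ir_distance + self.motif_length + 500)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("ies_length_range", "microhomology_length_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        for key in ("strains", "mut_strains"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted IES."""

    locus_id: str
    contig: str
    true_A: int
    true_B: int
    planted_motif: str | None
    left_motif_distance: int | None
    right_motif_distance: int | None
    microhomology: str

    @property
    def length(self) -> int:
        return self.true_B - self.true_A


def substream(seed: int, *tags) -> np.random.Generator:
    """Independent RNG stream derived by hashing (seed, tags)."""
    digest = hashlib.blake2b(
        "|".join([str(seed), *map(str, tags)]).encode(), digest_size=4
    ).digest()
    return np.random.default_rng(int.from_bytes(digest, "big") % 2**31)


def _contig_allocation(config: SimConfig) -> list[int]:
    base, extra = divmod(config.n_ies, config.n_contigs)
    return [base + (1 if i < extra else 0) for i in range(config.n_contigs)]


def generate_mic_genome(config: SimConfig) -> tuple[dict[str, str], list[TruthRecord]]:
    """Generate the MIC reference with planted IESs, IR motifs and microhomology.

    Returns the contig sequences and one TruthRecord per planted IES.  Every
    record is physically consistent with the emitted sequence: the motif and
    its reverse complement are present at the recorded flank distances, the
    microhomology string occurs immediately inside the A-end and immediately
    after the B-end, and [true_A, true_B) is the left-aligned (canonical)
    representation of the deletion.
    """
    rng = substream(config.seed, "genome")
    margin = config.placement_margin
    lo, hi = config.ies_length_range
    mh_lo, mh_hi = config.microhomology_length_range
    k = config.motif_length

    p = np.array(
        [
            (1 - config.gc_fraction) / 2,
            config.gc_fraction / 2,
            config.gc_fraction / 2,
            (1 - config.gc_fraction) / 2,
        ]
    )

    allocation = _contig_allocation(config)
    genome: dict[str, str] = {}
    truth: list[TruthRecord] = []
    idx = 0
    for ci, n_here in enumerate(allocation):
        name = f"contig{ci + 1}"
        L = config.contig_length
        if n_here * hi + (n_here + 1) * margin > L:
            raise ConfigurationError(
                f"cannot place {n_here} IESs of up to {hi} bp with {margin} bp "
                f"margins in a {L} bp contig"
            )
        arr = rng.choice(_BASES, size=L, p=p)

        lengths = rng.integers(lo, hi + 1, size=n_here)
        slack = L - int(lengths.sum()) - (n_here + 1) * margin
        gaps = rng.multinomial(slack, np.full(n_here + 1, 1.0 / (n_here + 1)))
        cursor = margin + int(gaps[0])
        for j in range(n_here):
            A = cursor
            B = A + int(lengths[j])
            cursor = B + margin + int(gaps[j + 1])

            motif = None
            dL = dR = None
            if config.ir_motif != "none" and rng.random() < config.motif_fraction:
                motif = config.ir_motif
                dL = config.ir_distance + int(
                    rng.integers(-config.ir_jitter, config.ir_jitter + 1)
                )
                dR = config.ir_distance + int(
                    rng.integers(-config.ir_jitter, config.ir_jitter + 1)
                )
                # left copy: IES-proximal base at A-1-dL; right copy is the
                # reverse complement with proximal base at B+dR.
                arr[A - dL - k : A - dL] = np.frombuffer(motif.encode(), np.uint8)
                arr[B + dR : B + dR + k] = np.frombuffer(
                    revcomp(motif).encode(), np.uint8
                )

            m = int(rng.integers(mh_lo, mh_hi + 1))
            if m:
                arr[B : B + m] = arr[A : A + m]
            # Canonical (left-aligned) truth: the base left of A must differ
            # from the base at B-1, otherwise [A,B) is not the left-most
            # representation of its own deletion product.
            if arr[A - 1] == arr[B - 1]:
                others = [b for b in _BASES.tolist() if b != arr[A - 1]]
                arr[B - 1] = others[int(rng.integers(len(others)))]

            seq_A = arr[A : A + m].tobytes().decode() if m else ""
            truth.append(
                TruthRecord(
                    locus_id=f"sim{idx:05d}",
                    contig=name,
                    true_A=A,
                    true_B=B,
                    planted_motif=motif,
                    left_motif_distance=dL,
                    right_motif_distance=dR,
                    microhomology=seq_A,
                )
            )
            idx += 1
        genome[name] = arr.tobytes().decode()
    return genome, truth


def generate_strain_deletions(
    truth: Sequence[TruthRecord], config: SimConfig, strain: str
) -> list[IESForm]:
    """Per-strain deletion forms: truth intervals with boundary jitter.

    Ends are perturbed by uniform integer jitter in ±boundary_jitter_wt
    (±boundary_jitter_mut for mutant strains at motif-marked loci).  Jitter
    that would shrink a form below 100 bp is resampled.  A `dup_fraction`
    of loci additionally receive a second, offset intra-strain form, and a
    `skip_fraction` of loci are absent from this strain entirely.
    """
    if strain not in config.strains:
        raise ConfigurationError(f"unknown strain {strain!r}")
    rng = substream(config.seed, "strain", strain)
    is_mut = strain in config.mut_strains
    forms: list[IESForm] = []
    for rec in truth:
        if rng.random() < config.skip_fraction:
            continue
        j = (
            config.boundary_jitter_mut
            if is_mut and rec.planted_motif is not None
            else config.boundary_jitter_wt
        )
        A, B = _jittered(rng, rec.true_A, rec.true_B, j)
        forms.append(
            IESForm(strain=strain, contig=rec.contig, A=A, B=B, source_id=rec.locus_id)
        )
        if rng.random() < config.dup_fraction and rec.length > 170:
            # Alternative intra-strain boundary: both ends shifted by the
            # same offset, large enough that its clip peaks never fall in
            # the refinement window of the primary form's peaks.
            d = int(rng.integers(160, min(240, rec.length - 10) + 1))
            forms.append(
                IESForm(
                    strain=strain,
                    contig=rec.contig,
                    A=rec.true_A + d,
                    B=rec.true_B + d,
                    source_id=rec.locus_id,
                )
            )
    return forms


def _jittered(rng: np.random.Generator, A: int, B: int, j: int) -> tuple[int, int]:
    if j == 0:
        return A, B
    while True:
        dA = int(rng.integers(-j, j + 1))
        dB = int(rng.integers(-j, j + 1))
        if (B + dB) - (A + dA) >= 100:
            return A + dA, B + dB


def emit_evidence(
    forms: Sequence[IESForm],
    config: SimConfig,
    contig_lengths: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Candidate deletion intervals plus clipped-read count profiles.

    Each form yields one candidate interval with ends displaced uniformly
    within ±candidate_displacement of the true form ends (emulating a
    coarse structural-variant call), and a dominant clip-count peak of
    `clip_support` reads at each true end.  Poisson background noise is
    added at `clip_noise_rate` sites per bp.  The `source_id` column keeps
    the truth linkage for testing; the refinement stage never reads it.
    """
    rng = substream(config.seed, "evidence")
    disp = config.candidate_displacement
    cand_rows = []
    clip_counts: dict[tuple[str, str], dict[int, int]] = {}
    for f in forms:
        cand_rows.append(
            {
                "strain": f.strain,
                "contig": f.contig,
                "start": f.A + int(rng.integers(-disp, disp + 1)),
                "end": f.B + int(rng.integers(-disp, disp + 1)),
                "uncertainty": disp,
                "source_id": f.source_id or "",
            }
        )
        counts = clip_counts.setdefault((f.strain, f.contig), {})
        counts[f.A] = counts.get(f.A, 0) + config.clip_support
        counts[f.B] = counts.get(f.B, 0) + config.clip_support

    if config.clip_noise_rate > 0 and contig_lengths is None:
        raise ConfigurationError("contig_lengths required when clip_noise_rate > 0")
    if config.clip_noise_rate > 0:
        for (strain, contig), counts in sorted(clip_counts.items()):
            L = contig_lengths[contig]
            n_noise = rng.binomial(L, config.clip_noise_rate)
            positions = rng.integers(0, L, size=n_noise)
            extra = 1 + rng.poisson(1.0, size=n_noise)
            for pos, c in zip(positions.tolist(), extra.tolist()):
                counts[pos] = counts.get(pos, 0) + int(c)

    candidates = pd.DataFrame(
        cand_rows, columns=["strain", "contig", "start", "end", "uncertainty", "source_id"]
    )
    clip_rows = [
        {"strain": strain, "contig": contig, "pos": pos, "clip_count": count}
        for (strain, contig), counts in sorted(clip_counts.items())
        for pos, count in sorted(counts.items())
    ]
    clips = pd.DataFrame(clip_rows, columns=["strain", "contig", "pos", "clip_count"])
    return candidates, clips


def simulate_experiment(
    config: SimConfig,
) -> tuple[dict[str, str], list[TruthRecord], list[IESForm], pd.DataFrame, pd.DataFrame]:
    """Run the whole generator: genome, truth, all strains' forms, evidence."""
    genome, truth = generate_mic_genome(config)
    forms: list[IESForm] = []
    for strain in config.strains:
        forms.extend(generate_strain_deletions(truth, config, strain))
    lengths = {name: len(seq) for name, seq in genome.items()}
    candidates, clips = emit_evidence(forms, config, lengths)
    return genome, truth, forms, candidates, clips
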