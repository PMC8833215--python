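"""Synthetic inputs with planted ground truth for every pipeline stage.

Three generators emulate the screen's three raw-data classes:

* bead sequencing reads — planted compounds, per-bead read replicates, and
  i.i.d. per-base substitution noise, split across the target (DY647) and
  counter-screen (TAMRA) channels;
* selection count tables — a starting library drawn multinomially from the
  uniform 4,096-fold distribution and a selected pool drawn with planted
  per-motif enrichment factors;
* a toy miRnome — stem-loop hairpins with annotated mature arms and loop
  motifs planted at chosen distances from Drosha/Dicer cleavage bonds, with
  log-normal expression.

Every generator is deterministic under its seed and returns a
machine-readable truth table; recovery tests consume the truth, never the
human-readable reports.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .decode import BeadRead, Channel
from .encoding import DELMember, EncodingScheme, encode_member
from .mirnome import MiRNAHairpin, Site
from .rna import (
    RNA_ALPHABET,
    ILLMember,
    LoopMotif,
    enumerate_ill,
    is_canonical_pair,
    reverse_complement,
)

DNA_ALPHABET = "ACGT"


# --------------------------------------------------------------------------
# bead reads
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BeadReadSpec:
    """Planted bead screen: {channel: {member: bead count}} plus noise."""

    planted_hits: Mapping[Channel, Mapping[DELMember, int]]
    noise_rate: float = 0.0
    reads_per_bead: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must lie in [0, 1]")
        if self.reads_per_bead < 1:
            raise ValueError("reads_per_bead must be >= 1")


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    if hit.any():
        # substitute with one of the three other bases, uniformly
        base_to_idx = {ord(b): i for i, b in enumerate(DNA_ALPHABET)}
        idxs = np.array([base_to_idx[b] for b in arr[hit]])
        new_idx = (idxs + rng.integers(1, 4, size=idxs.size)) % 4
        arr[hit] = np.array([ord(DNA_ALPHABET[i]) for i in new_idx], dtype=np.uint8)
    return arr.tobytes().decode()


def simulate_bead_reads(
    spec: BeadReadSpec, scheme: EncodingScheme
) -> tuple[list[BeadRead], pd.DataFrame]:
    """Generate reads for each planted bead plus a bead->compound truth table.

    Each bead emits ``reads_per_bead`` copies of its tag with i.i.d.
    substitutions at ``noise_rate``; bead ids are unique per channel.
    """
    rng = np.random.default_rng(spec.seed)
    reads: list[BeadRead] = []
    truth_rows = []
    bead_counter = 0
    for channel in sorted(spec.planted_hits, key=lambda c: c.value):
        plants = spec.planted_hits[channel]
        for member in sorted(plants, key=lambda m: m.compound_id):
            tag = encode_member(member, scheme)
            for _ in range(plants[member]):
                bead_id = f"bead{bead_counter:06d}"
                bead_counter += 1
                for r in range(spec.reads_per_bead):
                    reads.append(
                        BeadRead(
                            bead_id=bead_id,
                            channel=channel,
                            sequence=_mutate(tag, spec.noise_rate, rng),
                        )
                    )
                truth_rows.append(
                    {
                        "bead_id": bead_id,
                        "channel": channel.value,
                        "compound_key": member.tag_key,
                        "compound_id": member.compound_id,
                    }
                )
    truth = pd.DataFrame(truth_rows)
    return reads, truth


def write_fastq(reads: Sequence[BeadRead], path: str | Path) -> None:
    """FASTQ with the documented header dialect (constant Q40 qualities)."""
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            fh.write(
                f"@read{i:07d} bead={read.bead_id} channel={read.channel.value}\n"
                f"{read.sequence}\n+\n{'I' * len(read.sequence)}\n"
            )


# --------------------------------------------------------------------------
# selection counts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionSpec:
    """Planted enrichment: {canonical motif -> factor}, sequencing depth, seed."""

    planted_enrichments: Mapping[str, float]
    depth: int = 100_000
    compound: str = "compound_1"
    dose: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be positive")
        if any(f < 0 for f in self.planted_enrichments.values()):
            raise ValueError("enrichment factors must be >= 0")


def simulate_2dcs_counts(spec: SelectionSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw library and selected pools over the 4,096 folds.

    The starting library is multinomial(depth, uniform); the selected pool
    is multinomial(depth, probabilities proportional to the planted
    per-motif enrichment factors (default 1).  Returns the standard count
    table plus a truth table of planted factors.
    """
    rng = np.random.default_rng(spec.seed)
    members = list(enumerate_ill())
    motifs = [m.canonical for m in members]
    n = len(motifs)
    factors = np.ones(n)
    index = {motif: i for i, motif in enumerate(motifs)}
    for motif, f in spec.planted_enrichments.items():
        if motif not in index:
            raise ValueError(f"unknown motif {motif!r}")
        factors[index[motif]] = f
    lib_counts = rng.multinomial(spec.depth, np.full(n, 1.0 / n))
    sel_p = factors / factors.sum()
    sel_counts = rng.multinomial(spec.depth, sel_p)
    counts = pd.DataFrame(
        {
            "motif": motifs,
            "compound": spec.compound,
            "dose": spec.dose,
            "x_sel": sel_counts,
            "n_sel": spec.depth,
            "x_lib": lib_counts,
            "n_lib": spec.depth,
        }
    )
    truth = pd.DataFrame({"motif": motifs, "enrichment_factor": factors})
    return counts, truth


# --------------------------------------------------------------------------
# toy miRnome
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifPlacement:
    """Plant one motif window at a given distance from a cleavage bond."""

    motif: str                 # canonical "5'XXX/3'YYY"
    site: Site                 # DROSHA or DICER
    distance_nt: int = 0
    arm: str = "5p"            # which cut bond of the site ("5p" or "3p")


@dataclass(frozen=True)
class MirnomeSpec:
    n_hairpins: int = 10
    placements: Mapping[int, tuple[MotifPlacement, ...]] = field(default_factory=dict)
    stem_bp: int = 34          # columns in the fully paired reference stem
    arm_len: int = 22          # mature arm length (nt)
    arm_offset: int = 6        # stem columns basal of the 5p arm
    tail_len: int = 8
    apical_loop: str = "GUUUCAAG"
    expression_median_rpm: float = 500.0
    expression_sigma: float = 2.0  # log-normal sigma (natural log)
    disease_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arm_offset + self.arm_len > self.stem_bp:
            raise ValueError("mature arm does not fit in the stem")
        if not 0 <= self.disease_fraction <= 1:
            raise ValueError("disease_fraction must lie in [0, 1]")


def _motif_columns(motif: LoopMotif) -> list[tuple[str, str, bool]]:
    """Decompose a 3x3 window into aligned columns (top, bottom, paired?).

    Outer columns whose nucleotides form WC/GU pairs are treated as closing
    pairs of a smaller loop (e.g. 5'GAG/3'CCC is pair-loop-pair); columns
    in the unpaired core stay unpaired even if incidentally complementary.
    """
    cols = [(t, b) for t, b in zip(motif.top, motif.bottom)]
    n = len(cols)
    left = 0
    while left < n and is_canonical_pair(*cols[left]):
        left += 1
    right = 0
    while right < n - left and is_canonical_pair(*cols[n - 1 - right]):
        right += 1
    if left + right >= n:  # fully paired window: keep a 1-column core open
        raise ValueError(f"motif {motif.canonical} has no unpaired core")
    return [
        (t, b, i < left or i >= n - right) for i, (t, b) in enumerate(cols)
    ]


def _random_paired_column(rng: np.random.Generator) -> tuple[str, str]:
    pairs = [("G", "C"), ("C", "G"), ("A", "U"), ("U", "A")]
    return pairs[rng.integers(0, len(pairs))]


def simulate_mirnome(
    spec: MirnomeSpec,
) -> tuple[list[MiRNAHairpin], pd.DataFrame]:
    """Build toy hairpins with planted loop motifs at known cut distances.

    Each hairpin is a tail-stem-loop-stem-tail construct whose mature arms
    sit at fixed stem columns; a placement replaces stem columns with the
    motif's pair/loop columns such that the loop's nearest nucleotide lies
    exactly ``distance_nt`` from the requested cleavage bond.  Conflicting
    or out-of-range placements raise.  Returns hairpins plus a truth table
    of planted (hairpin, motif, site, distance) rows.
    """
    rng = np.random.default_rng(spec.seed)
    hairpins: list[MiRNAHairpin] = []
    truth_rows = []
    n_disease = int(round(spec.disease_fraction * spec.n_hairpins))
    for idx in range(spec.n_hairpins):
        hid = f"toy-mir-{idx + 1}"
        columns = [_random_paired_column(rng) for _ in range(spec.stem_bp)]
        paired = [True] * spec.stem_bp
        taken = [False] * spec.stem_bp

        # mature arms and cut bonds in *column* coordinates
        arm_start = spec.arm_offset                    # first column of the arms
        arm_stop = spec.arm_offset + spec.arm_len      # one past last column
        cut_columns = {
            (Site.DROSHA, "5p"): arm_start,   # basal boundary of the arms
            (Site.DROSHA, "3p"): arm_start,
            (Site.DICER, "5p"): arm_stop,     # apical boundary
            (Site.DICER, "3p"): arm_stop,
        }
        for placement in spec.placements.get(idx, ()):
            motif = LoopMotif.from_canonical(placement.motif)
            cols = _motif_columns(motif)
            loop_cols = [i for i, c in enumerate(cols) if not c[2]]
            cut_col = cut_columns[(placement.site, placement.arm)]
            # place so the loop's nearest column boundary is distance_nt from the cut
            if placement.site is Site.DROSHA:
                start = cut_col + placement.distance_nt - loop_cols[0]
            else:
                start = cut_col - placement.distance_nt - (loop_cols[-1] + 1)
            if start < 0 or start + len(cols) > spec.stem_bp:
                raise ValueError(
                    f"{hid}: placement of {placement.motif} at {placement.site.value} "
                    f"distance {placement.distance_nt} falls outside the stem"
                )
            if any(taken[start : start + len(cols)]):
                raise ValueError(f"{hid}: placements overlap at columns {start}+")
            for off, (t, b, is_pair) in enumerate(cols):
                columns[start + off] = (t, b)
                paired[start + off] = is_pair
                taken[start + off] = True
            truth_rows.append(
                {
                    "hairpin_id": hid,
                    "motif": placement.motif,
                    "site": placement.site.value,
                    "distance_nt": placement.distance_nt,
                    "loop_top_start": spec.tail_len + start + loop_cols[0],
                }
            )

        tail5 = "".join(rng.choice(list("ACU"), size=spec.tail_len))
        tail3 = "".join(rng.choice(list("ACU"), size=spec.tail_len))
        top = "".join(c[0] for c in columns)
        bottom = "".join(c[1] for c in columns)  # aligned; reversed in sequence
        seq = tail5 + top + spec.apical_loop + bottom[::-1] + tail3
        db = (
            "." * spec.tail_len
            + "".join("(" if p else "." for p in paired)
            + "." * len(spec.apical_loop)
            + "".join(")" if p else "." for p in reversed(paired))
            + "." * spec.tail_len
        )
        L = len(seq)
        # mature arms in 1-based sequence coordinates
        m5 = (spec.tail_len + arm_start + 1, spec.tail_len + arm_stop)
        bottom_block = spec.tail_len + spec.stem_bp + len(spec.apical_loop)
        m3 = (
            bottom_block + (spec.stem_bp - arm_stop) + 1,
            bottom_block + (spec.stem_bp - arm_start),
        )
        rpm = float(
            np.exp(rng.normal(np.log(spec.expression_median_rpm), spec.expression_sigma))
        )
        hairpins.append(
            MiRNAHairpin(
                id=hid,
                sequence=seq,
                dotbracket=db,
                mature5p=m5,
                mature3p=m3,
                expression_rpm=round(rpm, 1),
                disease_flag=idx < n_disease,
            )
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["hairpin_id", "motif", "site", "distance_nt", "loop_top_start"],
    )
    return hairpins, truth


# --------------------------------------------------------------------------
# JSON spec file
# --------------------------------------------------------------------------

def load_spec_json(path: str | Path) -> dict:
    """Parse a combined generator spec file (see docs for the schema)."""
    with open(path) as fh:
        return json.load(fh)
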