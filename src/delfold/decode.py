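"""Decode sequencing reads from sorted beads into library compounds.

Beads sorted in two fluorescence channels — DY647 (the RNA-fold library
target) and TAMRA (the base-paired counter screen) — carry PCR-amplified
encoding tags.  Pattern matching anchors on the primers, parses the three
fixed-position codon fields, and corrects up to a configurable number of
substitutions per codon by nearest-codon search (unique whenever the error
count is below half the design Hamming distance).  Beads are called by
majority vote over their reads, ranked by replicate class k (distinct beads
per compound), filtered for channel selectivity, and clustered by Tanimoto
similarity with a deterministic leader algorithm.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from Bio import SeqIO

from .encoding import (
    AcylPosition,
    DELMember,
    EncodingScheme,
    Fingerprint,
    FingerprintMode,
    HubStereo,
    fingerprint,
    hamming,
    tanimoto,
)


class Channel(str, enum.Enum):
    TARGET = "DY647"   # RNA-fold-library binding gate
    COUNTER = "TAMRA"  # base-paired counter-screen gate


class FailureReason(str, enum.Enum):
    NO_ANCHOR = "NO_ANCHOR"            # primer5/primer3 not found where expected
    BAD_LENGTH = "BAD_LENGTH"          # read shorter than the tag
    CODON_UNRESOLVED = "CODON_UNRESOLVED"  # no codon within tolerance
    CODON_AMBIGUOUS = "CODON_AMBIGUOUS"    # >1 codon at the minimal distance


@dataclass(frozen=True)
class BeadRead:
    bead_id: str
    channel: Channel
    sequence: str
    quality: tuple[int, ...] | None = None


@dataclass(frozen=True)
class DecodeFailure:
    reason: FailureReason

    def __bool__(self) -> bool:
        return False


@dataclass(frozen=True)
class TagTriple:
    """A successfully parsed tag: the stereo-collapsed compound identity."""

    r1_index: int
    acid_index: int
    acyl_position: AcylPosition

    def __bool__(self) -> bool:
        return True

    @property
    def key(self) -> str:
        return DELMember(
            self.r1_index, self.acid_index, self.acyl_position, HubStereo.S
        ).tag_key


def _nearest_codon(
    observed: str, table: Sequence[str], max_mismatch: int
) -> int | DecodeFailure:
    best_idx, best_d, ties = -1, len(observed) + 1, 0
    for i, codon in enumerate(table):
        d = hamming(observed, codon)
        if d < best_d:
            best_idx, best_d, ties = i, d, 1
        elif d == best_d:
            ties += 1
    if best_d > max_mismatch:
        return DecodeFailure(FailureReason.CODON_UNRESOLVED)
    if ties > 1:
        return DecodeFailure(FailureReason.CODON_AMBIGUOUS)
    return best_idx


def match_pattern(
    read: str,
    scheme: EncodingScheme,
    max_mismatch_per_codon: int = 1,
) -> TagTriple | DecodeFailure:
    """Parse one read into its tag triple, or a reason-coded failure.

    Primers are matched exactly; primer5 may occur anywhere in the read
    (adapters upstream are tolerated), and primer3 must sit at its fixed
    offset downstream.  Each codon field maps to the nearest table codon
    within ``max_mismatch_per_codon`` substitutions.
    """
    start = read.find(scheme.primer5)
    if start < 0:
        return DecodeFailure(FailureReason.NO_ANCHOR)
    tag = read[start : start + scheme.tag_length]
    if len(tag) < scheme.tag_length:
        return DecodeFailure(FailureReason.BAD_LENGTH)
    if not tag.endswith(scheme.primer3):
        return DecodeFailure(FailureReason.NO_ANCHOR)
    s_r1, s_acid, s_acyl = scheme.field_slices()
    r1 = _nearest_codon(tag[s_r1], scheme.r1_codons, max_mismatch_per_codon)
    if isinstance(r1, DecodeFailure):
        return r1
    acid = _nearest_codon(tag[s_acid], scheme.acid_codons, max_mismatch_per_codon)
    if isinstance(acid, DecodeFailure):
        return acid
    acyl = _nearest_codon(tag[s_acyl], scheme.acyl_codons, max_mismatch_per_codon)
    if isinstance(acyl, DecodeFailure):
        return acyl
    return TagTriple(r1, acid, AcylPosition.R2 if acyl == 0 else AcylPosition.R3)


@dataclass
class HitEntry:
    key: str
    r1_index: int
    acid_index: int
    acyl_position: AcylPosition
    channel: Channel
    bead_ids: tuple[str, ...]

    @property
    def k(self) -> int:
        """Replicate class: number of distinct beads calling this compound."""
        return len(self.bead_ids)


@dataclass
class HitTable:
    """Decoded compounds of one channel, keyed by tag-level compound key."""

    channel: Channel
    entries: dict[str, HitEntry] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: str) -> bool:
        return key in self.entries

    def __getitem__(self, key: str) -> HitEntry:
        return self.entries[key]

    def keys(self):
        return self.entries.keys()

    def values(self):
        return self.entries.values()

    @property
    def total_k(self) -> int:
        return sum(e.k for e in self.entries.values())


@dataclass
class DecodeStats:
    beads_total: int = 0
    beads_called: int = 0
    beads_dropped_no_decode: int = 0
    beads_dropped_tie: int = 0
    read_failures: dict[FailureReason, int] = field(default_factory=dict)
    dropped_beads: list[str] = field(default_factory=list)


def decode_beads(
    reads: Iterable[BeadRead],
    scheme: EncodingScheme,
    max_mismatch_per_codon: int = 1,
) -> tuple[dict[Channel, HitTable], DecodeStats]:
    """Call each bead's compound by majority vote over its decoded reads.

    Ties and beads with no decodable read are dropped and logged in the
    stats, never raised: decode statistics stay computable on noisy runs.
    """
    stats = DecodeStats()
    per_bead: dict[tuple[str, Channel], list[TagTriple]] = {}
    seen_beads: set[tuple[str, Channel]] = set()
    for read in reads:
        bead = (read.bead_id, read.channel)
        seen_beads.add(bead)
        result = match_pattern(read.sequence, scheme, max_mismatch_per_codon)
        if isinstance(result, DecodeFailure):
            stats.read_failures[result.reason] = (
                stats.read_failures.get(result.reason, 0) + 1
            )
            continue
        per_bead.setdefault(bead, []).append(result)

    tables = {ch: HitTable(channel=ch) for ch in Channel}
    stats.beads_total = len(seen_beads)
    for bead in sorted(seen_beads):
        bead_id, channel = bead
        triples = per_bead.get(bead, [])
        if not triples:
            stats.beads_dropped_no_decode += 1
            stats.dropped_beads.append(bead_id)
            continue
        votes: dict[TagTriple, int] = {}
        for t in triples:
            votes[t] = votes.get(t, 0) + 1
        top = max(votes.values())
        winners = [t for t, v in votes.items() if v == top]
        if len(winners) != 1:
            stats.beads_dropped_tie += 1
            stats.dropped_beads.append(bead_id)
            continue
        triple = winners[0]
        table = tables[channel]
        entry = table.entries.get(triple.key)
        if entry is None:
            table.entries[triple.key] = HitEntry(
                key=triple.key,
                r1_index=triple.r1_index,
                acid_index=triple.acid_index,
                acyl_position=triple.acyl_position,
                channel=channel,
                bead_ids=(bead_id,),
            )
        else:
            entry.bead_ids = entry.bead_ids + (bead_id,)
        stats.beads_called += 1
    return tables, stats


def selectivity_filter(target: HitTable, counter: HitTable) -> HitTable:
    """Keep target-channel compounds never seen in the counter channel.

    In-silico analogue of the two-color FACS gate (high target fluorescence,
    low counter fluorescence): a hard set difference on compound keys.
    """
    kept = {k: e for k, e in target.entries.items() if k not in counter}
    return HitTable(channel=target.channel, entries=kept)


@dataclass(frozen=True)
class Cluster:
    members: tuple[str, ...]
    representative: str
    size: int


def cluster_hits(
    hits: HitTable,
    threshold: float = 0.8,
    mode: FingerprintMode = FingerprintMode.BLOCK_ONEHOT,
    fingerprint_fn: Callable[[str], Fingerprint] | None = None,
) -> list[Cluster]:
    """Deterministic leader clustering of hits by Tanimoto similarity.

    Seeds are processed in descending replicate class k (ties broken
    lexicographically by compound key); a hit joins the first existing seed
    with similarity >= threshold.  The result is a partition invariant to
    input order.  The representative is the max-k member (lexicographic
    tie-break), which by the processing order is the seed itself.
    """
    if fingerprint_fn is None:
        def fingerprint_fn(key: str) -> Fingerprint:
            return fingerprint(DELMember.from_tag_key(key), mode)

    order = sorted(hits.values(), key=lambda e: (-e.k, e.key))
    fps = {e.key: fingerprint_fn(e.key) for e in order}
    seeds: list[str] = []
    membership: dict[str, list[str]] = {}
    for entry in order:
        for seed in seeds:
            if tanimoto(fps[entry.key], fps[seed]) >= threshold:
                membership[seed].append(entry.key)
                break
        else:
            seeds.append(entry.key)
            membership[entry.key] = [entry.key]

    clusters = []
    for seed in seeds:
        members = tuple(membership[seed])
        rep = min(members, key=lambda m: (-hits[m].k, m))
        clusters.append(Cluster(members=members, representative=rep, size=len(members)))
    clusters.sort(key=lambda c: (-c.size, -hits[c.representative].k, c.representative))
    return clusters


def hit_rate(events: int, beads_screened: int) -> float:
    """Sort events as a percentage of beads screened."""
    if beads_screened <= 0:
        raise ValueError("beads_screened must be positive")
    return 100.0 * events / beads_screened


def acylation_summary(hits: HitTable) -> dict[str, int]:
    """Descriptive count of hit beads by acylation route (secondary vs primary amine)."""
    out = {AcylPosition.R2.value: 0, AcylPosition.R3.value: 0}
    for e in hits.values():
        out[e.acyl_position.value] += e.k
    return out


# --- I/O ------------------------------------------------------------------

def _parse_header(description: str) -> tuple[str, Channel]:
    """Read-header dialect: ``... bead=<id> channel=<DY647|TAMRA>``."""
    fields = dict(
        tok.split("=", 1) for tok in description.split() if "=" in tok
    )
    if "bead" not in fields or "channel" not in fields:
        raise ValueError(f"header lacks bead=/channel= fields: {description!r}")
    return fields["bead"], Channel(fields["channel"])


def read_bead_reads(path: str | Path, fmt: str | None = None) -> list[BeadRead]:
    """Load bead reads from FASTQ or FASTA (format inferred from the suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in {".fq", ".fastq"} else "fasta"
    reads = []
    for rec in SeqIO.parse(str(path), fmt):
        bead_id, channel = _parse_header(rec.description)
        qual = rec.letter_annotations.get("phred_quality")
        reads.append(
            BeadRead(
                bead_id=bead_id,
                channel=channel,
                sequence=str(rec.seq),
                quality=tuple(qual) if qual else None,
            )
        )
    return reads


def write_hit_report(
    hits: HitTable,
    clusters: Sequence[Cluster],
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    """TSV hit report: compound_id, r1, acid, acyl_position, k, cluster_id, is_representative."""
    import pandas as pd

    cluster_of = {}
    rep_of = {}
    for i, cl in enumerate(clusters):
        for m in cl.members:
            cluster_of[m] = i
            rep_of[m] = m == cl.representative
    rows = sorted(hits.values(), key=lambda e: (cluster_of.get(e.key, -1), -e.k, e.key))
    df = pd.DataFrame(
        {
            "compound_id": [e.key for e in rows],
            "r1": [e.r1_index for e in rows],
            "acid": [e.acid_index for e in rows],
            "acyl_position": [e.acyl_position.value for e in rows],
            "k": [e.k for e in rows],
            "cluster_id": [cluster_of.get(e.key, -1) for e in rows],
            "is_representative": [rep_of.get(e.key, False) for e in rows],
        }
    )
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)
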