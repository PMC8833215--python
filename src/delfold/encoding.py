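"""DNA encoding of a split-pool combinatorial small-molecule library.

The library is assembled in two encoded cycles on bead: one of 96 amino
acids (cycle 1, R1), a central azido-proline hub used as a stoichiometric
mixture of two diastereomers, and one of 192 carboxylic acids (cycle 2)
acylated either onto the hub's secondary amine (R2) or, after azide
reduction, onto the primary amine (R3).  Each chemistry choice except the
hub stereochemistry is recorded by ligating a short DNA codon, so the full
tag reads

    primer5 + codon(R1) + codon(acid) + codon(acyl position) + primer3

and two hub diastereomers share a tag.  The library therefore holds
96 x 192 x 2 x 2 = 73,728 members encoded by 36,864 distinct tags.

Codon tables are designed with a guaranteed minimum pairwise Hamming
distance so that single sequencing errors inside a codon remain uniquely
correctable.
"""

from __future__ import annotations

import enum
import functools
import itertools
import json
from dataclasses import dataclass, field
from typing import Callable, Iterator, Mapping, Sequence

import numpy as np

DNA_ALPHABET = "ACGT"

#: cardinalities of the two encoded chemistry cycles
N_AMINO_ACIDS = 96
N_ACIDS = 192

DEFAULT_CODON_LENGTH = 8
DEFAULT_MIN_HAMMING = 3
DEFAULT_SCHEME_SEED = 20220202


class Cycle(str, enum.Enum):
    AMINO_ACID = "amino_acid"
    ACID = "acid"


class AcylPosition(str, enum.Enum):
    """Which amine of the hub received the cycle-2 acid."""

    R2 = "R2"  # secondary amine, Fmoc-deprotection route
    R3 = "R3"  # primary amine, azide-reduction route


class HubStereo(str, enum.Enum):
    S = "S"
    R = "R"


class FingerprintMode(str, enum.Enum):
    BLOCK_ONEHOT = "block_onehot"
    STRUCTURE = "structure"


class CodonDesignError(ValueError):
    """Requested codon table is infeasible or could not be constructed."""


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def assign_codons(
    n: int,
    codon_length: int,
    min_hamming: int,
    seed: int,
    max_tries: int = 200_000,
) -> list[str]:
    """Design ``n`` DNA codons with pairwise Hamming distance >= ``min_hamming``.

    Uses a seeded rejection-sampling greedy: random candidate codons are
    accepted when far enough from all accepted ones.  Deterministic for a
    given seed.  Raises :class:`CodonDesignError` when the request is
    provably infeasible (Singleton bound) or the search exhausts its budget.
    """
    if n < 1 or codon_length < 1:
        raise CodonDesignError("n and codon_length must be positive")
    if min_hamming < 1 or min_hamming > codon_length:
        raise CodonDesignError(
            f"min_hamming must lie in [1, codon_length]; got {min_hamming}"
        )
    # Singleton bound: a code of length L and distance d has at most 4^(L-d+1) words.
    if n > 4 ** (codon_length - min_hamming + 1):
        raise CodonDesignError(
            f"{n} codons of length {codon_length} at Hamming distance "
            f">= {min_hamming} exceed the Singleton bound "
            f"4^{codon_length - min_hamming + 1}"
        )
    rng = np.random.default_rng(seed)
    accepted = np.empty((0, codon_length), dtype=np.int8)
    for _ in range(max_tries):
        cand = rng.integers(0, 4, size=codon_length, dtype=np.int8)
        if accepted.shape[0] == 0 or (accepted != cand).sum(axis=1).min() >= min_hamming:
            accepted = np.vstack([accepted, cand])
            if accepted.shape[0] == n:
                return ["".join(DNA_ALPHABET[b] for b in row) for row in accepted]
    raise CodonDesignError(
        f"could not place {n} codons (length {codon_length}, "
        f"min Hamming {min_hamming}) within {max_tries} draws"
    )


def verify_codon_table(codons: Sequence[str], min_hamming: int) -> None:
    """Brute-force all-pairs check of the Hamming contract (raises on violation)."""
    for a, b in itertools.combinations(codons, 2):
        if hamming(a, b) < min_hamming:
            raise CodonDesignError(
                f"codons {a} and {b} are at distance {hamming(a, b)} < {min_hamming}"
            )


@dataclass(frozen=True)
class BuildingBlock:
    """One chemistry building block with its DNA codon."""

    cycle: Cycle
    index: int
    name: str
    codon: str
    structure: str | None = None  # SMILES, optional

    def __post_init__(self) -> None:
        limit = N_AMINO_ACIDS if self.cycle is Cycle.AMINO_ACID else N_ACIDS
        if not 0 <= self.index < limit:
            raise ValueError(f"{self.cycle.value} index {self.index} out of range")


@dataclass(frozen=True)
class EncodingScheme:
    """Tag layout: primers plus positional codon fields (R1, acid, acyl position)."""

    primer5: str
    primer3: str
    codon_length: int
    min_hamming: int
    r1_codons: tuple[str, ...]
    acid_codons: tuple[str, ...]
    acyl_codons: tuple[str, ...]  # (codon for R2, codon for R3)
    blocks: Mapping[Cycle, tuple[BuildingBlock, ...]] | None = field(
        default=None, compare=False
    )

    def __post_init__(self) -> None:
        for table in (self.r1_codons, self.acid_codons, self.acyl_codons):
            for c in table:
                if len(c) != self.codon_length:
                    raise ValueError(f"codon {c} is not {self.codon_length} nt")
            verify_codon_table(table, self.min_hamming)
        if len(self.acyl_codons) != 2:
            raise ValueError("acyl position table must hold exactly two codons")
        for primer in (self.primer5, self.primer3):
            for c in (*self.r1_codons, *self.acid_codons, *self.acyl_codons):
                if c in primer:
                    raise ValueError(f"primer contains codon {c} as a substring")

    @property
    def n_r1(self) -> int:
        return len(self.r1_codons)

    @property
    def n_acid(self) -> int:
        return len(self.acid_codons)

    @property
    def tag_length(self) -> int:
        return len(self.primer5) + 3 * self.codon_length + len(self.primer3)

    def field_slices(self) -> tuple[slice, slice, slice]:
        """Codon-field positions inside the tag, in (R1, acid, acyl) order."""
        o = len(self.primer5)
        L = self.codon_length
        return (
            slice(o, o + L),
            slice(o + L, o + 2 * L),
            slice(o + 2 * L, o + 3 * L),
        )

    @classmethod
    def generate(
        cls,
        n_r1: int = N_AMINO_ACIDS,
        n_acid: int = N_ACIDS,
        codon_length: int = DEFAULT_CODON_LENGTH,
        min_hamming: int = DEFAULT_MIN_HAMMING,
        seed: int = DEFAULT_SCHEME_SEED,
        primer5: str = "ACGTGAGTCTGACTGC",
        primer3: str = "GCTCAGACTGAGTGCA",
    ) -> "EncodingScheme":
        """Design a full scheme: one joint codon pool split across the three fields.

        Designing all codons jointly keeps every cross-field pair at the
        design distance too, which is stronger than the per-table contract
        and costs nothing.  Seeds are retried deterministically if a drawn
        codon happens to occur inside a primer.
        """
        n_total = n_r1 + n_acid + 2
        for attempt in range(20):
            pool = assign_codons(n_total, codon_length, min_hamming, seed + attempt)
            if any(c in primer5 or c in primer3 for c in pool):
                continue
            return cls(
                primer5=primer5,
                primer3=primer3,
                codon_length=codon_length,
                min_hamming=min_hamming,
                r1_codons=tuple(pool[:n_r1]),
                acid_codons=tuple(pool[n_r1 : n_r1 + n_acid]),
                acyl_codons=tuple(pool[n_r1 + n_acid :]),
            )
        raise CodonDesignError("no primer-compatible codon pool found")

    # --- JSON config I/O -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "primer5": self.primer5,
                "primer3": self.primer3,
                "codon_length": self.codon_length,
                "min_hamming": self.min_hamming,
                "r1_codons": list(self.r1_codons),
                "acid_codons": list(self.acid_codons),
                "acyl_codons": list(self.acyl_codons),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "EncodingScheme":
        d = json.loads(text)
        return cls(
            primer5=d["primer5"],
            primer3=d["primer3"],
            codon_length=int(d["codon_length"]),
            min_hamming=int(d["min_hamming"]),
            r1_codons=tuple(d["r1_codons"]),
            acid_codons=tuple(d["acid_codons"]),
            acyl_codons=tuple(d["acyl_codons"]),
        )


@functools.lru_cache(maxsize=1)
def default_scheme() -> EncodingScheme:
    """The full 96 x 192 scheme with default design parameters (cached)."""
    return EncodingScheme.generate()


@dataclass(frozen=True, order=True)
class DELMember:
    """One library member: cycle-1 block, hub stereochemistry, acylation route, cycle-2 block."""

    r1_index: int
    acid_index: int
    acyl_position: AcylPosition
    hub_stereo: HubStereo

    @property
    def compound_id(self) -> str:
        """Bijective identifier of the full 4-tuple (includes stereochemistry)."""
        return (
            f"R1_{self.r1_index:03d}-AC_{self.acid_index:03d}"
            f"-{self.acyl_position.value}-{self.hub_stereo.value}"
        )

    @property
    def tag_key(self) -> str:
        """Tag-level key: what sequencing can resolve (stereo collapsed)."""
        return (
            f"R1_{self.r1_index:03d}-AC_{self.acid_index:03d}"
            f"-{self.acyl_position.value}"
        )

    @staticmethod
    def from_tag_key(key: str, hub_stereo: HubStereo = HubStereo.S) -> "DELMember":
        r1_part, acid_part, acyl_part = key.split("-")
        return DELMember(
            r1_index=int(r1_part.split("_")[1]),
            acid_index=int(acid_part.split("_")[1]),
            acyl_position=AcylPosition(acyl_part),
            hub_stereo=hub_stereo,
        )


def enumerate_del(scheme: EncodingScheme | None = None) -> Iterator[DELMember]:
    """Yield every library member: all (R1, acid, acyl position, diastereomer) tuples.

    Tag diversity is half the member count because the hub stereocenter is
    not encoded.
    """
    scheme = scheme or default_scheme()
    for r1 in range(scheme.n_r1):
        for acid in range(scheme.n_acid):
            for pos in (AcylPosition.R2, AcylPosition.R3):
                for stereo in (HubStereo.S, HubStereo.R):
                    yield DELMember(r1, acid, pos, stereo)


def encode_member(member: DELMember, scheme: EncodingScheme | None = None) -> str:
    """Emit the member's DNA encoding tag. Diastereomers encode identically."""
    scheme = scheme or default_scheme()
    if not 0 <= member.r1_index < scheme.n_r1:
        raise IndexError(f"r1_index {member.r1_index} outside codon table")
    if not 0 <= member.acid_index < scheme.n_acid:
        raise IndexError(f"acid_index {member.acid_index} outside codon table")
    acyl_idx = 0 if member.acyl_position is AcylPosition.R2 else 1
    return (
        scheme.primer5
        + scheme.r1_codons[member.r1_index]
        + scheme.acid_codons[member.acid_index]
        + scheme.acyl_codons[acyl_idx]
        + scheme.primer3
    )


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length bit set used for Tanimoto similarity."""

    bits: frozenset[int]
    length: int

    def __post_init__(self) -> None:
        if any(b < 0 or b >= self.length for b in self.bits):
            raise ValueError("bit index outside fingerprint length")


def fingerprint(
    member: DELMember,
    mode: FingerprintMode = FingerprintMode.BLOCK_ONEHOT,
    *,
    smiles: str | None = None,
    n_bits: int = 2048,
    radius: int = 2,
) -> Fingerprint:
    """Fingerprint a member for similarity clustering.

    BLOCK_ONEHOT sets exactly one bit per encoded degree of freedom (cycle-1
    block, cycle-2 block, acylation position, hub stereochemistry); it needs
    no chemical structures and makes Tanimoto similarity a simple count of
    shared building blocks.  STRUCTURE delegates to an rdkit Morgan
    (circular substructure) fingerprint of a supplied assembled SMILES.
    """
    if mode is FingerprintMode.BLOCK_ONEHOT:
        length = N_AMINO_ACIDS + N_ACIDS + 2 + 2
        acyl_idx = 0 if member.acyl_position is AcylPosition.R2 else 1
        stereo_idx = 0 if member.hub_stereo is HubStereo.S else 1
        bits = frozenset(
            {
                member.r1_index,
                N_AMINO_ACIDS + member.acid_index,
                N_AMINO_ACIDS + N_ACIDS + acyl_idx,
                N_AMINO_ACIDS + N_ACIDS + 2 + stereo_idx,
            }
        )
        return Fingerprint(bits=bits, length=length)
    if smiles is None:
        raise ValueError("STRUCTURE fingerprints require an assembled SMILES")
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bv = gen.GetFingerprint(mol)
    return Fingerprint(bits=frozenset(bv.GetOnBits()), length=n_bits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Jaccard similarity of two bit sets; 0 by convention when both are empty."""
    if a.length != b.length:
        raise ValueError(f"fingerprint length mismatch: {a.length} vs {b.length}")
    union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    return len(a.bits & b.bits) / union


def write_block_table(blocks: Sequence[BuildingBlock], path: str) -> None:
    """TSV building-block table: cycle, index, name, smiles, codon."""
    import pandas as pd

    pd.DataFrame(
        {
            "cycle": [b.cycle.value for b in blocks],
            "index": [b.index for b in blocks],
            "name": [b.name for b in blocks],
            "smiles": [b.structure or "" for b in blocks],
            "codon": [b.codon for b in blocks],
        }
    ).to_csv(path, sep="\t", index=False)


def read_block_table(path: str) -> list[BuildingBlock]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"smiles": str}, keep_default_na=False)
    return [
        BuildingBlock(
            cycle=Cycle(cyc),
            index=int(idx),
            name=str(nam),
            codon=str(cod),
            structure=str(smi) or None,
        )
        for cyc, idx, nam, smi, cod in zip(
            df["cycle"], df["index"], df["name"], df["smiles"], df["codon"]
        )
    ]
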