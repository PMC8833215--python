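"""Map privileged RNA loop motifs onto miRNA hairpins and their processing sites.

A primary miRNA hairpin is cropped by Drosha at the base of the stem and by
Dicer near the apical loop; the four cleavage bonds are derivable from the
annotated mature-arm coordinates (miRBase convention, 1-based inclusive):

    Drosha cuts:  5' end of the 5p arm | 3' end of the 3p arm
    Dicer cuts:   3' end of the 5p arm | 5' end of the 3p arm

A ligand whose privileged internal-loop motifs occur at (or within a small
window of) a processing site is a candidate biogenesis inhibitor for that
miRNA; candidates are prioritized by mature-miRNA expression (reads per
million), since occupancy — and hence functional effect — scales with
target abundance.
"""

from __future__ import annotations

import enum
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .rna import (
    HairpinStructure,
    InternalLoop,
    LoopMotif,
    WindowError,
    extract_internal_loops,
    nussinov_fold,
    window_3x3,
)

DEFAULT_SITE_WINDOW = 2  # nt from a cleavage bond still counted as "in" the site


class Site(str, enum.Enum):
    DROSHA = "DROSHA"
    DICER = "DICER"
    NONE = "NONE"


@dataclass(frozen=True)
class MiRNAHairpin:
    """A pri/pre-miRNA hairpin with structure, arm annotation and expression.

    Mature-arm intervals are 1-based inclusive (file convention); bond
    indices elsewhere count nucleotides 5' of the cut, so bond b lies
    between positions b and b+1 (1-based).
    """

    id: str
    sequence: str
    dotbracket: str | None
    mature5p: tuple[int, int] | None
    mature3p: tuple[int, int] | None
    expression_rpm: float | None = None
    disease_flag: bool = False

    def __post_init__(self) -> None:
        L = len(self.sequence)
        if self.dotbracket is not None and len(self.dotbracket) != L:
            raise ValueError(f"{self.id}: structure length differs from sequence")
        for name, iv in (("mature5p", self.mature5p), ("mature3p", self.mature3p)):
            if iv is not None:
                s, e = iv
                if not (1 <= s <= e <= L):
                    raise ValueError(f"{self.id}: {name} interval {iv} out of bounds")
        if self.mature5p and self.mature3p and self.mature5p[1] >= self.mature3p[0]:
            raise ValueError(f"{self.id}: 5p arm must precede 3p arm")
        if self.expression_rpm is not None and self.expression_rpm < 0:
            raise ValueError(f"{self.id}: expression must be >= 0")


@dataclass(frozen=True)
class ProcessingSites:
    """Cleavage bond indices (None where the arm annotation is missing)."""

    drosha_5p: int | None  # 5' of the 5p arm
    drosha_3p: int | None  # 3' of the 3p arm
    dicer_5p: int | None   # 3' of the 5p arm
    dicer_3p: int | None   # 5' of the 3p arm

    def bonds(self, site: Site) -> list[int]:
        if site is Site.DROSHA:
            return [b for b in (self.drosha_5p, self.drosha_3p) if b is not None]
        if site is Site.DICER:
            return [b for b in (self.dicer_5p, self.dicer_3p) if b is not None]
        return []


def processing_sites(h: MiRNAHairpin) -> ProcessingSites:
    """Derive Drosha/Dicer cleavage bonds from the mature-arm intervals."""
    if h.mature5p is None and h.mature3p is None:
        raise ValueError(f"{h.id}: no mature arm annotated")
    d5 = di5 = d3 = di3 = None
    if h.mature5p is not None:
        s, e = h.mature5p
        d5, di5 = s - 1, e
    if h.mature3p is not None:
        s, e = h.mature3p
        di3, d3 = s - 1, e
    return ProcessingSites(drosha_5p=d5, drosha_3p=d3, dicer_5p=di5, dicer_3p=di3)


@dataclass(frozen=True)
class TargetHit:
    """One motif occurrence in one hairpin loop."""

    hairpin_id: str
    motif: str                      # canonical "5'XXX/3'YYY"
    loop_top_start: int             # 0-based
    loop_size: tuple[int, int]
    site: Site
    distance_nt: int
    expression_rpm: float | None
    compounds: tuple[str, ...]
    disease_flag: bool = False


def _loop_bond_distance(loop: InternalLoop, bond: int) -> int:
    """Distance (nt) from the loop to a cleavage bond; 0 when the loop spans it.

    Bond b (1-based convention) separates 0-based positions b-1 and b; a
    nucleotide run [s, e) touches bonds s..e, so the distance is 0 when the
    bond falls inside or at the edge of the run on either strand.
    """
    best = math.inf
    for positions in (loop.top_positions(), loop.bottom_positions()):
        if len(positions) == 0:
            continue
        s, e = positions.start, positions.stop
        if s <= bond <= e:
            return 0
        best = min(best, abs(bond - s), abs(bond - e))
    return int(best)


def nearest_site(
    loop: InternalLoop, sites: ProcessingSites, window: int = DEFAULT_SITE_WINDOW
) -> tuple[Site, int]:
    """Nearest processing site and its distance; NONE beyond the window."""
    best_site, best_d = Site.NONE, math.inf
    for site in (Site.DROSHA, Site.DICER):
        for bond in sites.bonds(site):
            d = _loop_bond_distance(loop, bond)
            if d < best_d:
                best_site, best_d = site, d
    if best_d is math.inf:
        return Site.NONE, -1
    if best_d > window:
        return Site.NONE, int(best_d)
    return best_site, int(best_d)


def mine_motifs(
    hairpins: Iterable[MiRNAHairpin],
    motif_table: Mapping[str, Sequence[str]],
    site_window: int = DEFAULT_SITE_WINDOW,
) -> list[TargetHit]:
    """Scan hairpins for privileged-motif loop windows and annotate sites.

    ``motif_table`` maps canonical "5'XXX/3'YYY" strings to the compounds
    predicted to bind them.  Every internal loop (windowed to the library's
    3x3 frame) is matched; each (hairpin, loop, motif) occurrence yields one
    hit, with the nearest Drosha/Dicer bond and its distance.  Hairpins
    without a supplied structure are folded by base-pair maximization with a
    warning — supplied structures are always preferred.
    """
    hits: list[TargetHit] = []
    for h in hairpins:
        db = h.dotbracket
        if db is None:
            warnings.warn(
                f"{h.id}: no structure supplied; folding by base-pair maximization",
                stacklevel=2,
            )
            db = nussinov_fold(h.sequence)
        structure = HairpinStructure(sequence=h.sequence, dotbracket=db)
        try:
            sites = processing_sites(h)
        except ValueError:
            sites = ProcessingSites(None, None, None, None)
        for loop in extract_internal_loops(structure, include_bulges=False):
            a, b = loop.size
            if a > 3 or b > 3:
                continue
            try:
                windows = window_3x3(loop)
            except WindowError:
                continue
            matched = {
                w.canonical for w in windows if w.canonical in motif_table
            }
            for canonical in sorted(matched):
                site, dist = nearest_site(loop, sites, site_window)
                hits.append(
                    TargetHit(
                        hairpin_id=h.id,
                        motif=canonical,
                        loop_top_start=loop.top_start,
                        loop_size=loop.size,
                        site=site,
                        distance_nt=dist,
                        expression_rpm=h.expression_rpm,
                        compounds=tuple(motif_table[canonical]),
                        disease_flag=h.disease_flag,
                    )
                )
    return hits


def fold_difference(rpm_a: float, rpm_b: float) -> float:
    """Expression ratio to two significant figures; inf when the divisor is 0."""
    if rpm_b == 0:
        return math.inf
    ratio = rpm_a / rpm_b
    if ratio == 0:
        return 0.0
    digits = -int(math.floor(math.log10(abs(ratio)))) + 1
    return round(ratio, digits)


def rank_targets(hits: Sequence[TargetHit]) -> pd.DataFrame:
    """Rank hits by expression within each (motif, site) group.

    Hits without expression rank last and are flagged.  ``fold_vs_next``
    gives the ratio of each hit's rpm to the next-ranked hit's (two
    significant figures; inf over a zero-rpm competitor).
    """
    rows = []
    for hit in hits:
        rows.append(
            {
                "motif": hit.motif,
                "site": hit.site.value,
                "hairpin_id": hit.hairpin_id,
                "expression_rpm": hit.expression_rpm,
                "expression_missing": hit.expression_rpm is None,
                "distance_nt": hit.distance_nt,
                "disease_flag": hit.disease_flag,
                "compounds": ",".join(hit.compounds),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["_rpm"] = df["expression_rpm"].fillna(-1.0)
    df = (
        df.sort_values(["motif", "site", "_rpm"], ascending=[True, True, False])
        .drop(columns="_rpm")
        .reset_index(drop=True)
    )
    folds = []
    for (_, _), grp in df.groupby(["motif", "site"], sort=False):
        rpms = grp["expression_rpm"].tolist()
        for i, rpm in enumerate(rpms):
            nxt = rpms[i + 1] if i + 1 < len(rpms) else None
            if rpm is None or nxt is None or pd.isna(rpm) or pd.isna(nxt):
                folds.append(float("nan"))
            else:
                folds.append(fold_difference(rpm, nxt))
    df["fold_vs_next"] = folds
    return df


def mining_summary(
    privileged_motifs: Iterable[str], hits: Sequence[TargetHit]
) -> dict:
    """Counts of motifs found in the hairpin set and in disease processing sites.

    ``pct_in_mirnome`` is the nearest-integer percentage of privileged
    motifs with at least one loop-window occurrence anywhere in the set;
    ``n_in_processing_sites`` counts motifs overlapping a Drosha/Dicer site
    of a disease-flagged hairpin.
    """
    motifs = sorted(set(privileged_motifs))
    found = {h.motif for h in hits}
    in_sites = {
        h.motif
        for h in hits
        if h.site is not Site.NONE and h.disease_flag
    }
    per_motif = {
        m: len({h.hairpin_id for h in hits if h.motif == m}) for m in motifs
    }
    n = len(motifs)
    n_found = sum(1 for m in motifs if m in found)
    return {
        "n_motifs": n,
        "n_in_mirnome": n_found,
        "pct_in_mirnome": round(100.0 * n_found / n) if n else 0,
        "n_in_processing_sites": sum(1 for m in motifs if m in in_sites),
        "per_motif_mirna_counts": per_motif,
    }


# --- I/O: FASTA + Vienna + GFF3 (miRBase dialect) + expression TSV --------

def write_hairpin_fasta(hairpins: Sequence[MiRNAHairpin], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(h.sequence), id=h.id, description="") for h in hairpins
    ]
    SeqIO.write(records, str(path), "fasta")


def write_mature_gff3(hairpins: Sequence[MiRNAHairpin], path: str | Path) -> None:
    """miRBase-style GFF3: one miRNA_primary_transcript per hairpin plus
    miRNA features with ``ID``/``Derives_from`` attributes, 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for h in hairpins:
            L = len(h.sequence)
            fh.write(
                f"{h.id}\t.\tmiRNA_primary_transcript\t1\t{L}\t.\t+\t.\t"
                f"ID={h.id};Name={h.id}\n"
            )
            for arm, iv in (("5p", h.mature5p), ("3p", h.mature3p)):
                if iv is None:
                    continue
                fh.write(
                    f"{h.id}\t.\tmiRNA\t{iv[0]}\t{iv[1]}\t.\t+\t.\t"
                    f"ID={h.id}-{arm};Name={h.id}-{arm};Derives_from={h.id}\n"
                )


def read_mature_gff3(path: str | Path) -> dict[str, dict[str, tuple[int, int]]]:
    """Mature-arm intervals per hairpin id: {hairpin: {"5p"|"3p": (start, end)}}."""
    arms: dict[str, dict[str, tuple[int, int]]] = {}
    for line in open(path):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9 or fields[2] != "miRNA":
            continue
        attrs = dict(
            kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
        )
        parent = attrs.get("Derives_from")
        name = attrs.get("ID", "")
        if parent is None:
            continue
        arm = "5p" if name.endswith("5p") else "3p" if name.endswith("3p") else None
        if arm is None:
            continue
        arms.setdefault(parent, {})[arm] = (int(fields[3]), int(fields[4]))
    return arms


def write_expression_tsv(hairpins: Sequence[MiRNAHairpin], path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [h.id for h in hairpins],
            "rpm": [h.expression_rpm for h in hairpins],
            "disease_flag": [h.disease_flag for h in hairpins],
        }
    ).to_csv(path, sep="\t", index=False)


def load_hairpins(
    fasta_path: str | Path,
    vienna_path: str | Path | None = None,
    gff3_path: str | Path | None = None,
    expression_path: str | Path | None = None,
) -> list[MiRNAHairpin]:
    """Assemble hairpin records from their standard-format component files."""
    from .rna import read_vienna

    structures = read_vienna(vienna_path) if vienna_path else {}
    arms = read_mature_gff3(gff3_path) if gff3_path else {}
    expr: dict[str, float] = {}
    disease: dict[str, bool] = {}
    if expression_path:
        df = pd.read_csv(expression_path, sep="\t")
        expr = dict(zip(df["id"].astype(str), df["rpm"].astype(float)))
        if "disease_flag" in df.columns:
            disease = dict(zip(df["id"].astype(str), df["disease_flag"].astype(bool)))
    hairpins = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        hid = rec.id
        struct = structures.get(hid)
        hairpins.append(
            MiRNAHairpin(
                id=hid,
                sequence=str(rec.seq).replace("T", "U"),
                dotbracket=struct.dotbracket if struct else None,
                mature5p=arms.get(hid, {}).get("5p"),
                mature3p=arms.get(hid, {}).get("3p"),
                expression_rpm=expr.get(hid),
                disease_flag=disease.get(hid, False),
            )
        )
    return hairpins


def write_target_report(hits: Sequence[TargetHit], path: str | Path, header_comment: str | None = None) -> None:
    df = rank_targets(hits)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_summary_json(summary: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
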