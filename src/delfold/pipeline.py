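"""End-to-end synthetic pipeline run: simulate -> decode -> enrich -> mine.

The default run plants a known screen — selective and promiscuous bead
compounds, fold-enriched motifs in the selection pool, and one privileged
motif at a synthetic Drosha processing site — then executes every stage and
reports both the stage outputs and their recovery against the plant.  This
is the package's own integration harness; all sizes are chosen to emulate
the screen's working regime (sequencing depth 1e5, 4,096-fold library,
handfuls of planted hits) while running in seconds.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .decode import (
    Channel,
    cluster_hits,
    decode_beads,
    selectivity_filter,
    write_hit_report,
)
from .encoding import AcylPosition, DELMember, HubStereo, default_scheme
from .enrichment import call_privileged, privileged_sets, write_results
from .mirnome import (
    Site,
    mine_motifs,
    mining_summary,
    write_expression_tsv,
    write_hairpin_fasta,
    write_mature_gff3,
    write_summary_json,
    write_target_report,
)
from .rna import HairpinStructure, enumerate_ill, write_vienna
from .simulate import (
    BeadReadSpec,
    MirnomeSpec,
    MotifPlacement,
    SelectionSpec,
    simulate_2dcs_counts,
    simulate_bead_reads,
    simulate_mirnome,
    write_fastq,
)

#: default planted-screen shape
N_SELECTIVE = 10
N_PROMISCUOUS = 5
BEADS_PER_COMPOUND = 3
N_ENRICHED_MOTIFS = 10
ENRICHMENT_FACTOR = 10.0
SELECTION_DEPTH = 100_000
DROSHA_MOTIF = "5'GAG/3'CCC"


def planted_members(n: int, scheme=None) -> list[DELMember]:
    """A deterministic spread of library members used as plants."""
    scheme = scheme or default_scheme()
    return [
        DELMember(
            r1_index=(13 * i) % scheme.n_r1,
            acid_index=(29 * i) % scheme.n_acid,
            acyl_position=AcylPosition.R2 if i % 2 == 0 else AcylPosition.R3,
            hub_stereo=HubStereo.S,
        )
        for i in range(n)
    ]


def planted_motifs(n: int, include: str = DROSHA_MOTIF) -> list[str]:
    """n distinct canonical motifs, spread over the library, containing ``include``."""
    all_motifs = [m.canonical for m in enumerate_ill()]
    step = len(all_motifs) // n
    chosen = [all_motifs[1 + i * step] for i in range(n)]
    if include not in chosen:
        chosen[0] = include
    return chosen


def run_default_pipeline(
    seed: int = 0,
    cutoff: float = 4.0,
    site_window: int = 2,
    tanimoto_threshold: float = 0.8,
    noise_rate: float = 0.0,
    out_dir: Path | None = None,
) -> dict:
    """Run the full planted pipeline; optionally persist stage artifacts.

    Returns a summary dict whose headline numbers (bead recall, selective
    set, privileged sensitivity, mining hits) are recomputed from the stage
    outputs, never copied from the plant.
    """
    scheme = default_scheme()
    rng_seed = int(seed) % (2**31 - 1)

    # --- stage 1: bead screen -------------------------------------------
    members = planted_members(N_SELECTIVE + N_PROMISCUOUS, scheme)
    selective_members = members[:N_SELECTIVE]
    promiscuous_members = members[N_SELECTIVE:]
    bead_spec = BeadReadSpec(
        planted_hits={
            Channel.TARGET: {m: BEADS_PER_COMPOUND for m in members},
            Channel.COUNTER: {m: BEADS_PER_COMPOUND for m in promiscuous_members},
        },
        noise_rate=noise_rate,
        seed=rng_seed,
    )
    reads, bead_truth = simulate_bead_reads(bead_spec, scheme)
    tables, stats = decode_beads(reads, scheme)
    selective = selectivity_filter(tables[Channel.TARGET], tables[Channel.COUNTER])
    clusters = cluster_hits(selective, threshold=tanimoto_threshold)

    truth_target = bead_truth[bead_truth["channel"] == Channel.TARGET.value]
    called = tables[Channel.TARGET]
    correct_beads = 0
    for row in truth_target.itertuples(index=False):
        entry = called.entries.get(row.compound_key)
        if entry is not None and row.bead_id in entry.bead_ids:
            correct_beads += 1
    bead_recall = correct_beads / len(truth_target)

    planted_selective_keys = {m.tag_key for m in selective_members}
    selective_exact = set(selective.keys()) == planted_selective_keys

    # --- stage 2: selection enrichment ----------------------------------
    motifs = planted_motifs(N_ENRICHED_MOTIFS)
    sel_spec = SelectionSpec(
        planted_enrichments={m: ENRICHMENT_FACTOR for m in motifs},
        depth=SELECTION_DEPTH,
        compound="compound_1",
        seed=rng_seed + 1,
    )
    counts, enrich_truth = simulate_2dcs_counts(sel_spec)
    results = call_privileged(counts, cutoff=cutoff)
    sets = privileged_sets(results)
    called_privileged = sets["compound_1"]
    sensitivity = len(called_privileged & set(motifs)) / len(motifs)
    false_positives = len(called_privileged - set(motifs))

    # --- stage 3: miRnome mining ----------------------------------------
    mir_spec = MirnomeSpec(
        n_hairpins=8,
        placements={0: (MotifPlacement(DROSHA_MOTIF, Site.DROSHA, 0),)},
        seed=rng_seed + 2,
    )
    hairpins, mir_truth = simulate_mirnome(mir_spec)
    motif_table = {m: ("compound_1",) for m in called_privileged}
    hits = mine_motifs(hairpins, motif_table, site_window=site_window)
    summary_mining = mining_summary(motif_table.keys(), hits)
    drosha_hits = [
        h for h in hits if h.motif == DROSHA_MOTIF and h.site is Site.DROSHA
    ]

    summary = {
        "beads_total": stats.beads_total,
        "beads_called": stats.beads_called,
        "bead_recall": bead_recall,
        "n_selective_called": len(selective),
        "selective_set_exact": bool(selective_exact),
        "n_clusters": len(clusters),
        "privileged_called": len(called_privileged),
        "privileged_sensitivity": sensitivity,
        "privileged_false_positives": false_positives,
        "mirnome": summary_mining,
        "drosha_site_hits": len(drosha_hits),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for ch in Channel:
            write_fastq([r for r in reads if r.channel is ch], out / f"{ch.value}.fastq")
        bead_truth.to_csv(out / "truth_beads.tsv", sep="\t", index=False)
        write_hit_report(selective, clusters, out / "hits.tsv")
        counts.to_csv(out / "counts.tsv", sep="\t", index=False)
        enrich_truth.to_csv(out / "truth_enrichment.tsv", sep="\t", index=False)
        write_results(results, out / "enrichment.tsv")
        write_hairpin_fasta(hairpins, out / "hairpins.fasta")
        write_vienna(
            [(h.id, HairpinStructure(h.sequence, h.dotbracket)) for h in hairpins],
            out / "hairpins.db",
        )
        write_mature_gff3(hairpins, out / "mature.gff3")
        write_expression_tsv(hairpins, out / "expression.tsv")
        mir_truth.to_csv(out / "truth_mirnome.tsv", sep="\t", index=False)
        write_target_report(hits, out / "targets.tsv")
    return summary
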