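"""Processing-site derivation, motif mining, ranking, and mining summaries."""

import math

import pytest

from delfold import (
    MiRNAHairpin,
    Site,
    fold_difference,
    mine_motifs,
    mining_summary,
    processing_sites,
    rank_targets,
)
from delfold.mirnome import (
    load_hairpins,
    read_mature_gff3,
    write_expression_tsv,
    write_hairpin_fasta,
    write_mature_gff3,
)
from delfold.rna import HairpinStructure, write_vienna
from delfold.simulate import MirnomeSpec, MotifPlacement, simulate_mirnome


def toy_hairpin(**overrides):
    defaults = dict(
        id="toy",
        sequence="A" * 100,
        dotbracket=None,
        mature5p=(10, 31),
        mature3p=(65, 86),
        expression_rpm=100.0,
    )
    defaults.update(overrides)
    return MiRNAHairpin(**defaults)


class TestProcessingSites:
    def test_cut_bonds_from_arm_intervals(self):
        sites = processing_sites(toy_hairpin())
        # Drosha cuts the bonds 9|10 and 86|87; Dicer cuts 31|32 and 64|65
        assert (sites.drosha_5p, sites.drosha_3p) == (9, 86)
        assert (sites.dicer_5p, sites.dicer_3p) == (31, 64)

    def test_missing_3p_arm_partial_sites(self):
        sites = processing_sites(toy_hairpin(mature3p=None))
        assert sites.drosha_5p == 9 and sites.dicer_5p == 31
        assert sites.drosha_3p is None and sites.dicer_3p is None

    def test_no_arms_rejected(self):
        with pytest.raises(ValueError):
            processing_sites(toy_hairpin(mature5p=None, mature3p=None))

    def test_drosha_flanks_dicer(self):
        sites = processing_sites(toy_hairpin())
        assert sites.drosha_5p < sites.dicer_5p <= sites.dicer_3p < sites.drosha_3p

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError):
            toy_hairpin(mature5p=(0, 31))
        with pytest.raises(ValueError):
            toy_hairpin(mature5p=(40, 31))
        with pytest.raises(ValueError):
            toy_hairpin(mature5p=(10, 70))  # overlaps the 3p arm

    def test_gff3_round_trip_preserves_cuts(self, tmp_path):
        spec = MirnomeSpec(n_hairpins=3, seed=4)
        hairpins, _ = simulate_mirnome(spec)
        path = tmp_path / "mature.gff3"
        write_mature_gff3(hairpins, path)
        arms = read_mature_gff3(path)
        for h in hairpins:
            assert arms[h.id]["5p"] == h.mature5p
            assert arms[h.id]["3p"] == h.mature3p
            reloaded = MiRNAHairpin(
                id=h.id, sequence=h.sequence, dotbracket=h.dotbracket,
                mature5p=arms[h.id]["5p"], mature3p=arms[h.id]["3p"],
            )
            assert processing_sites(reloaded) == processing_sites(h)


GAG_CCC = "5'GAG/3'CCC"


class TestMineMotifs:
    def test_planted_drosha_motif_found_at_distance_zero(self):
        spec = MirnomeSpec(
            n_hairpins=2,
            placements={0: (MotifPlacement(GAG_CCC, Site.DROSHA, 0),)},
            seed=1,
        )
        hairpins, truth = simulate_mirnome(spec)
        hits = mine_motifs(hairpins, {GAG_CCC: ("compound_9",)})
        assert len(hits) == 1
        hit = hits[0]
        assert hit.hairpin_id == truth["hairpin_id"].iloc[0]
        assert hit.site is Site.DROSHA
        assert hit.distance_nt == 0
        assert hit.compounds == ("compound_9",)

    def test_no_matching_loops_no_hits(self):
        spec = MirnomeSpec(n_hairpins=3, seed=2)
        hairpins, _ = simulate_mirnome(spec)
        assert mine_motifs(hairpins, {GAG_CCC: ()}) == []

    def test_tandem_copies_give_two_hits(self):
        # two copies of the same loop near the Drosha site of one hairpin,
        # mirroring the tandem-binding-site topology
        spec = MirnomeSpec(
            n_hairpins=1,
            placements={
                0: (
                    MotifPlacement(GAG_CCC, Site.DROSHA, 0),
                    MotifPlacement(GAG_CCC, Site.DROSHA, 5),
                )
            },
            seed=5,
        )
        hairpins, _ = simulate_mirnome(spec)
        hits = mine_motifs(hairpins, {GAG_CCC: ("compound_9",)})
        assert len(hits) == 2
        assert {h.motif for h in hits} == {GAG_CCC}
        sites = sorted((h.site, h.distance_nt) for h in hits)
        assert sites[0] == (Site.DROSHA, 0)
        # the second copy sits 5 nt away: outside the default 2-nt window
        assert sites[1] == (Site.NONE, 5)

    def test_distance_window_configurable(self):
        spec = MirnomeSpec(
            n_hairpins=1,
            placements={0: (MotifPlacement(GAG_CCC, Site.DICER, 2),)},
            seed=6,
        )
        hairpins, _ = simulate_mirnome(spec)
        hits = mine_motifs(hairpins, {GAG_CCC: ()}, site_window=2)
        assert hits[0].site is Site.DICER and hits[0].distance_nt == 2
        hits = mine_motifs(hairpins, {GAG_CCC: ()}, site_window=1)
        assert hits[0].site is Site.NONE

    def test_hit_coordinates_self_consistent(self):
        from delfold.rna import extract_internal_loops, window_3x3

        spec = MirnomeSpec(
            n_hairpins=2,
            placements={1: (MotifPlacement(GAG_CCC, Site.DICER, 1),)},
            seed=7,
        )
        hairpins, _ = simulate_mirnome(spec)
        hits = mine_motifs(hairpins, {GAG_CCC: ()})
        for hit in hits:
            h = next(x for x in hairpins if x.id == hit.hairpin_id)
            loops = extract_internal_loops(
                HairpinStructure(h.sequence, h.dotbracket), include_bulges=False
            )
            loop = next(l for l in loops if l.top_start == hit.loop_top_start)
            assert hit.motif in {w.canonical for w in window_3x3(loop)}

    def test_unstructured_hairpin_folded_with_warning(self):
        h = toy_hairpin(sequence="GGGGGAAAACCCCC" + "A" * 86, dotbracket=None,
                        mature5p=(2, 5), mature3p=(60, 70))
        with pytest.warns(UserWarning, match="no structure"):
            mine_motifs([h], {GAG_CCC: ()})


class TestRankTargets:
    def _hits(self, rpms):
        from delfold.mirnome import TargetHit

        return [
            TargetHit(
                hairpin_id=f"mir-{i}", motif=GAG_CCC, loop_top_start=0,
                loop_size=(1, 1), site=Site.DROSHA, distance_nt=0,
                expression_rpm=rpm, compounds=("c",),
            )
            for i, rpm in enumerate(rpms)
        ]

    def test_expression_ratio_two_sig_figs(self):
        assert fold_difference(85_900, 391) == 220
        assert fold_difference(100.0, 100.0) == 1.0

    def test_zero_rpm_competitor_flagged_infinite(self):
        assert math.isinf(fold_difference(100.0, 0.0))

    def test_ranking_descends_by_expression(self):
        df = rank_targets(self._hits([391.0, 85_900.0]))
        assert df["expression_rpm"].tolist() == [85_900.0, 391.0]
        assert df["fold_vs_next"].iloc[0] == 220

    def test_missing_expression_ranks_last(self):
        df = rank_targets(self._hits([50.0, None, 100.0]))
        assert df["expression_rpm"].tolist()[:2] == [100.0, 50.0]
        assert df["expression_missing"].tolist() == [False, False, True]


class TestMiningSummary:
    def _hit(self, motif, site=Site.NONE, disease=False, hairpin="mir-1"):
        from delfold.mirnome import TargetHit

        return TargetHit(
            hairpin_id=hairpin, motif=motif, loop_top_start=0, loop_size=(1, 1),
            site=site, distance_nt=0 if site is not Site.NONE else 99,
            expression_rpm=1.0, compounds=(), disease_flag=disease,
        )

    def test_percentage_rounding(self):
        motifs = [f"m{i}" for i in range(212)]
        hits = [self._hit(m) for m in motifs[:123]]
        summary = mining_summary(motifs, hits)
        assert summary["n_in_mirnome"] == 123
        assert summary["pct_in_mirnome"] == 58

    def test_zero_hits(self):
        summary = mining_summary(["m1", "m2"], [])
        assert summary["pct_in_mirnome"] == 0
        assert summary["n_in_processing_sites"] == 0

    def test_planted_fraction(self):
        motifs = [f"m{i}" for i in range(10)]
        hits = [self._hit(m) for m in motifs[:3]]
        assert mining_summary(motifs, hits)["pct_in_mirnome"] == 30

    def test_processing_site_requires_disease_flag(self):
        hits = [
            self._hit("m1", Site.DROSHA, disease=True),
            self._hit("m2", Site.DICER, disease=False),
            self._hit("m3", Site.NONE, disease=True),
        ]
        summary = mining_summary(["m1", "m2", "m3"], hits)
        assert summary["n_in_processing_sites"] == 1

    def test_per_motif_mirna_counts(self):
        hits = [
            self._hit("m1", hairpin="mir-1"),
            self._hit("m1", hairpin="mir-2"),
            self._hit("m1", hairpin="mir-2"),
        ]
        summary = mining_summary(["m1", "m2"], hits)
        assert summary["per_motif_mirna_counts"] == {"m1": 2, "m2": 0}


def test_load_hairpins_from_component_files(tmp_path):
    spec = MirnomeSpec(
        n_hairpins=3,
        placements={0: (MotifPlacement(GAG_CCC, Site.DROSHA, 0),)},
        seed=9,
    )
    hairpins, _ = simulate_mirnome(spec)
    write_hairpin_fasta(hairpins, tmp_path / "h.fasta")
    write_vienna(
        [(h.id, HairpinStructure(h.sequence, h.dotbracket)) for h in hairpins],
        tmp_path / "h.db",
    )
    write_mature_gff3(hairpins, tmp_path / "h.gff3")
    write_expression_tsv(hairpins, tmp_path / "expr.tsv")
    loaded = load_hairpins(
        tmp_path / "h.fasta", tmp_path / "h.db", tmp_path / "h.gff3",
        tmp_path / "expr.tsv",
    )
    assert len(loaded) == len(hairpins)
    by_id = {h.id: h for h in loaded}
    for h in hairpins:
        g = by_id[h.id]
        assert g.sequence == h.sequence
        assert g.dotbracket == h.dotbracket
        assert (g.mature5p, g.mature3p) == (h.mature5p, h.mature3p)
        assert g.expression_rpm == pytest.approx(h.expression_rpm)
        assert g.disease_flag == h.disease_flag
    # mining the reloaded files reproduces the planted hit
    hits = mine_motifs(loaded, {GAG_CCC: ()})
    assert len(hits) == 1 and hits[0].site is Site.DROSHA
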