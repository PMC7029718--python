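"""End-to-end colocalization model, results object, summaries and CLI."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import coloctk as ct
from coloctk.cli import main as cli_main
from coloctk.model import summarize_by_tissue
from coloctk.stats import EnrichmentResult, ContingencyTable


def fit_default(coll, spec, **kwargs):
    q = ct.make_query(spec, coll)
    m = ct.Colocalization(
        q, coll.profiles, coll.hierarchy,
        options=kwargs.pop("options", ct.QueryOptions(genome_size=spec.genome_size)),
        profile_intervals=coll.intervals, **kwargs,
    )
    return m.fit()


class TestPipeline:
    def test_planted_target_ranks_first_enriched(self, default_spec, default_collection):
        res = fit_default(default_collection, default_spec)
        top = res.results[0]
        assert top.profile_id == default_spec.planted_target
        assert top.classification == "enriched"
        assert res.profile_table.iloc[0]["rank"] == 1

    def test_query_outside_all_profiles_yields_no_enrichment(self, default_collection):
        # rejection-sample query intervals that touch no profile interval
        all_ivs = [iv for ivs in default_collection.intervals.values() for iv in ivs]
        idx = ct.build_index(all_ivs)
        spec = ct.FixtureSpec(fraction_inside=0.0, seed=7)
        query = []
        stream = 0
        while len(query) < spec.query_size:
            stream += 1
            cand = ct.make_query(
                ct.FixtureSpec(fraction_inside=0.0, seed=7 + stream),
                default_collection,
            )
            query.extend(iv for iv in cand if idx.n_overlapping(iv) == 0)
        query = query[: spec.query_size]
        m = ct.Colocalization(
            query, default_collection.profiles, default_collection.hierarchy,
            options=ct.QueryOptions(genome_size=spec.genome_size),
            profile_intervals=default_collection.intervals,
        )
        res = m.fit()
        assert all(r.classification != "enriched" for r in res.results)

    def test_sorted_non_increasing_combo(self, default_spec, default_collection):
        res = fit_default(default_collection, default_spec)
        combos = [r.combo_score for r in res.results]
        assert combos == sorted(combos, reverse=True)

    def test_empty_tissue_selection_is_error(self, default_spec, default_collection):
        q = ct.make_query(default_spec, default_collection)
        opts = ct.QueryOptions(
            genome_size=default_spec.genome_size, tissues=frozenset({"liver"}),
            categories=frozenset({"histone_modification"}),
        )
        m = ct.Colocalization(q, default_collection.profiles,
                              default_collection.hierarchy, options=opts,
                              profile_intervals=default_collection.intervals)
        with pytest.raises(ValueError, match="zero profiles"):
            m.fit()

    def test_tissue_filter_does_not_change_retained_statistics(
        self, default_spec, default_collection
    ):
        full = fit_default(default_collection, default_spec)
        opts = ct.QueryOptions(
            genome_size=default_spec.genome_size, tissues=frozenset({"blood"})
        )
        sub = fit_default(default_collection, default_spec, options=opts)
        full_by_id = {r.profile_id: r for r in full.results}
        assert len(sub.results) < len(full.results)
        for r in sub.results:
            assert r.combo_score == full_by_id[r.profile_id].combo_score

    def test_disabling_curation_never_drops_profiles(self):
        spec = ct.FixtureSpec(n_profiles=4, replicates=8, n_outliers=3,
                              intervals_per_profile=20, jitter=100, seed=11)
        coll = ct.make_profile_collection(spec)
        with_cur = fit_default(coll, spec, curate=True)
        without = fit_default(coll, spec, curate=False)
        assert len(without.results) >= len(with_cur.results)
        assert len(without.results) == len(coll.profiles)

    def test_group_median_and_best_flag(self):
        spec = ct.FixtureSpec(n_profiles=0, replicates=4, n_outliers=0,
                              intervals_per_profile=20, seed=3, fraction_inside=0.0,
                              planted_target=None)
        coll = ct.make_profile_collection(spec)
        res = fit_default(coll, spec, curate=False)
        g = list(res.group_results.values())[0]
        member_combos = sorted(r.combo_score for r in res.results)
        assert g.median_combo == pytest.approx(
            0.5 * (member_combos[1] + member_combos[2])
        )
        table = res.profile_table
        assert table["best_in_group"].sum() == 1
        assert table.loc[table["best_in_group"], "profile_id"].iloc[0] == g.best_profile_id

    def test_from_files_matches_in_memory(self, disk_collection):
        spec, coll = disk_collection
        qtext = ct.write_bed(ct.make_query(spec, coll))
        import tempfile, pathlib
        with tempfile.TemporaryDirectory() as d:
            qp = pathlib.Path(d) / "q.bed"
            qp.write_text(qtext)
            m = ct.Colocalization.from_files(
                qp, coll.manifest_path, coll.hierarchy_path,
                options=ct.QueryOptions(genome_size=spec.genome_size),
            )
            res = m.fit()
        mem = fit_default(coll, spec)
        pd.testing.assert_frame_equal(res.profile_table, mem.profile_table)

    def test_determinism_byte_identical_csv(self, tmp_path, default_spec,
                                            default_collection):
        p1 = fit_default(default_collection, default_spec).save(tmp_path / "r1")
        p2 = fit_default(default_collection, default_spec).save(tmp_path / "r2")
        assert p1["profiles"].read_bytes() == p2["profiles"].read_bytes()

    def test_summary_reports_counts(self, default_spec, default_collection):
        res = fit_default(default_collection, default_spec)
        text = res.summary()
        assert "Enriched: 1" in text and "Profiles evaluated: 20" in text


class TestTissueSummary:
    def _res(self, combo, cls, tissue, sub=None):
        return EnrichmentResult(
            profile_id="x", overlaps=0, query_hits=0, p_value=0.5, odds_ratio=1.0,
            combo_score=combo, classification=cls,
            table=ContingencyTable(1, 1, 1, 1, 4), tissue=tissue, sub_tissue=sub,
        )

    def test_counts_per_tissue(self):
        h = ct.load_tissue_hierarchy({"blood": [], "liver": []})
        rows = [self._res(10, "enriched", "blood")] * 3 + [
            self._res(-5, "depleted", "liver")
        ]
        df = summarize_by_tissue(rows, h).set_index("tissue_id")
        assert df.loc["blood", "n_enriched"] == 3
        assert df.loc["liver", "n_depleted"] == 1

    def test_subtissue_rolls_up_to_parent(self):
        h = ct.load_tissue_hierarchy({"blood": ["monocyte"]})
        df = summarize_by_tissue(
            [self._res(8, "enriched", "blood", sub="monocyte")], h
        ).set_index("tissue_id")
        assert df.loc["monocyte", "n_enriched"] == 1
        assert df.loc["blood", "n_enriched"] == 1

    def test_empty_results(self):
        h = ct.load_tissue_hierarchy({"blood": []})
        assert summarize_by_tissue([], h).empty

    def test_sign_counts_alongside_cutoff_counts(self):
        h = ct.load_tissue_hierarchy({"blood": []})
        df = summarize_by_tissue(
            [self._res(3, "neutral", "blood")], h
        ).set_index("tissue_id")
        assert df.loc["blood", "n_positive"] == 1
        assert df.loc["blood", "n_neutral"] == 1


class TestCalibration:
    def test_zero_queries_rejected(self, default_collection):
        with pytest.raises(ValueError):
            ct.calibrate_cutoffs(
                default_collection.profiles, default_collection.hierarchy,
                n_queries=0, query_size=10, interval_length=200,
                genome_size=10_000_000,
                chromosomes=default_collection.spec.chromosomes, seed=1,
            )

    def test_null_fraction_small_and_reproducible(self, default_collection):
        spec = default_collection.spec
        kw = dict(
            n_queries=50, query_size=100, interval_length=200,
            genome_size=spec.genome_size, chromosomes=spec.chromosomes,
            seed=7, profile_intervals=default_collection.intervals,
            options=ct.QueryOptions(genome_size=spec.genome_size),
        )
        r1 = ct.calibrate_cutoffs(default_collection.profiles,
                                  default_collection.hierarchy, **kw)
        r2 = ct.calibrate_cutoffs(default_collection.profiles,
                                  default_collection.hierarchy, **kw)
        assert np.array_equal(r1.combos, r2.combos)
        assert r1.exceedance[5.0] < 0.10


class TestCLI:
    def test_run_and_curate_roundtrip(self, tmp_path, disk_collection):
        spec, coll = disk_collection
        qp = tmp_path / "q.bed"
        qp.write_text(ct.write_bed(ct.make_query(spec, coll)))
        runner = CliRunner()
        out = tmp_path / "res"
        r = runner.invoke(cli_main, [
            "run", "--query", str(qp), "--manifest", str(coll.manifest_path),
            "--hierarchy", str(coll.hierarchy_path),
            "--genome-size", str(spec.genome_size), "--out", str(out),
        ])
        assert r.exit_code == 0, r.output
        table = pd.read_csv(out / "prioritization.csv")
        assert table.iloc[0]["profile_id"] == spec.planted_target

        report = tmp_path / "curation.tsv"
        r = runner.invoke(cli_main, [
            "curate", "--manifest", str(coll.manifest_path),
            "--hierarchy", str(coll.hierarchy_path),
            "--genome-size", str(spec.genome_size), "--out", str(report),
        ])
        assert r.exit_code == 0, r.output
        assert report.read_text().startswith("group_id\tprofile_id\tretained")
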