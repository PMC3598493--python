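"""Orchestration, output tables, Circos files, and the CLI."""

import json
from pathlib import Path

import pytest
from click.testing import CliRunner

from coloclust.cli import main
from coloclust.clusters import find_clusters
from coloclust.genome import load_annotation, write_annotation_tsv
from coloclust.homology import map_query
from coloclust.report import (
    RunConfig,
    read_clusters_tsv,
    read_distance_hist_tsv,
    run_analyze,
    run_compare,
    write_circos,
    write_clusters_tsv,
    write_distance_hist_tsv,
)
from coloclust.synthetic import SyntheticSpec, derive_species, generate_genome

from helpers import annotation_from_ranks

SPEC = SyntheticSpec(
    n_genes=150,
    n_chromosomes=3,
    n_planted_clusters=4,
    cluster_size=3,
    intra_cluster_gaps=1,
    seed=17,
)


@pytest.fixture(scope="module")
def fixture_genome():
    ann, query = generate_genome(SPEC)
    derived, table = derive_species(ann, query, 0.0, "twin", seed=1)
    return ann, query, derived, table


class TestRunAnalyze:
    def test_summary_accounts_for_query_and_writes_tables(self, fixture_genome, tmp_path):
        ann, query, derived, table = fixture_genome
        config = RunConfig(d=2, p_min=0.01, seed=9, ref_species="ref", output_dir=tmp_path)
        summary = run_analyze(
            config, {"ref": ann, "twin": derived}, query + ["missing_gene"], table
        )
        rep = summary.species["ref"]
        assert rep.n_found == len(query)
        assert rep.missing == ["missing_gene"]
        assert rep.n_clusters == SPEC.n_planted_clusters
        assert rep.error is None
        for f in ("clusters.tsv", "distance_hist.tsv", "size_hist.tsv", "pvalues.tsv"):
            assert (tmp_path / "ref" / f).exists()
            assert (tmp_path / "twin" / f).exists()
        payload = json.loads((tmp_path / "summary.json").read_text())
        assert payload["parameters"]["n_iterations"] == 100
        assert payload["species"]["ref"]["genes_found"] == len(query)

    def test_same_seed_runs_are_byte_identical(self, fixture_genome, tmp_path):
        ann, query, _, _ = fixture_genome
        outputs = []
        for run in ("one", "two"):
            outdir = tmp_path / run
            config = RunConfig(d=2, p_min=0.01, seed=5, ref_species="ref", output_dir=outdir)
            run_analyze(config, {"ref": ann}, query)
            outputs.append(
                {p.name: p.read_bytes() for p in (outdir / "ref").iterdir()}
            )
        assert outputs[0] == outputs[1]

    def test_two_distant_genes_give_no_clusters(self, tmp_path):
        ann = annotation_from_ranks({"chrA": [1], "chrB": [1]})
        # pad so the null model has slots to shuffle over
        config = RunConfig(d=2, p_min=0.5, seed=1, ref_species="ref", output_dir=tmp_path)
        summary = run_analyze(config, {"ref": ann}, ["chrA_g1", "chrB_g1"])
        rep = summary.species["ref"]
        assert rep.n_clusters == 0
        assert rep.n_singletons == 2
        hist = read_distance_hist_tsv(tmp_path / "ref" / "distance_hist.tsv")
        assert hist.counts == {}

    def test_failure_in_one_species_does_not_abort_others(self, fixture_genome, tmp_path):
        ann, query, derived, table = fixture_genome
        config = RunConfig(ref_species="ref", output_dir=tmp_path, p_min=0.1)
        summary = run_analyze(
            config, {"ref": ann, "ghost": derived}, query, table
        )  # "ghost" has no homology entries
        assert summary.species["ref"].error is None
        assert summary.species["ghost"].error is not None


class TestRoundTrips:
    def test_clusters_tsv_round_trip(self, fixture_genome, tmp_path):
        ann, query, _, _ = fixture_genome
        cs = find_clusters(ann, query, d=2)
        path = tmp_path / "clusters.tsv"
        write_clusters_tsv(cs, path)
        back = read_clusters_tsv(path, ann, d=2)
        assert [c.gene_ids for c in back.clusters] == [c.gene_ids for c in cs.clusters]
        assert [g.gene_id for g in back.singletons] == [g.gene_id for g in cs.singletons]

    def test_distance_hist_round_trip(self, fixture_genome, tmp_path):
        from coloclust.clusters import distance_distribution

        ann, query, _, _ = fixture_genome
        hist = distance_distribution(ann, query)
        path = tmp_path / "hist.tsv"
        write_distance_hist_tsv(hist, path)
        assert read_distance_hist_tsv(path).counts == hist.counts


class TestRunCompare:
    def test_identity_comparison_scores_one(self, fixture_genome, tmp_path):
        ann, query, derived, table = fixture_genome
        ref_cs = find_clusters(ann, query, d=2)
        sq = map_query(table, query, "twin")
        twin_cs = find_clusters(derived, sq.target_genes, d=2)
        config = RunConfig(ref_species="ref", output_dir=tmp_path)
        result = run_compare(
            config,
            {"ref": ref_cs, "twin": twin_cs},
            {"twin": sq.back_map},
        )
        assert result.scores["ref"] == 1.0
        assert result.scores["twin"] == 1.0
        assert (tmp_path / "conservation.tsv").exists()


class TestWriteCircos:
    def test_track_line_counts(self, fixture_genome, tmp_path):
        ann, query, _, _ = fixture_genome
        cs = find_clusters(ann, query, d=2)
        paths = write_circos(ann, cs, tmp_path)
        karyotype, hist, labels = paths
        assert len(karyotype.read_text().splitlines()) == len(ann.chromosomes)
        assert len(hist.read_text().splitlines()) == cs.n_clusters
        assert len(labels.read_text().splitlines()) == sum(c.size for c in cs.clusters)
        first = karyotype.read_text().splitlines()[0].split()
        assert first[:2] == ["chr", "-"]

    def test_histogram_value_is_cluster_size(self, tmp_path):
        ann = annotation_from_ranks({"chr1": [1, 2, 3]})
        cs = find_clusters(ann, ["chr1_g1", "chr1_g2", "chr1_g3"], d=0)
        _, hist, _ = write_circos(ann, cs, tmp_path)
        (line,) = hist.read_text().splitlines()
        assert line.split()[-1] == "3"

    def test_empty_cluster_set_warns_and_writes_nothing(self, tmp_path):
        ann = annotation_from_ranks({"chr1": [1, 9]})
        cs = find_clusters(ann, ["chr1_g1", "chr1_g9"], d=2)
        with pytest.warns(UserWarning):
            paths = write_circos(ann, cs, tmp_path / "sub")
        assert paths == []
        assert not (tmp_path / "sub").exists()


class TestCli:
    def test_simulate_analyze_compare_circos(self, tmp_path):
        runner = CliRunner()
        sim = tmp_path / "sim"
        out = tmp_path / "out"
        r = runner.invoke(main, [
            "simulate", "--genes", "150", "--chroms", "3", "--clusters", "4",
            "--cluster-size", "3", "--gaps", "1", "--rearrange", "0.0",
            "--seed", "7", "--out", str(sim),
        ])
        assert r.exit_code == 0, r.output
        r = runner.invoke(main, [
            "analyze",
            "--annotation", f"ref={sim / 'ref.tsv'}",
            "--annotation", f"derived1={sim / 'derived1.tsv'}",
            "--query", str(sim / "query.txt"),
            "--homology", str(sim / "homology.tsv"),
            "--ref-species", "ref",
            "--d", "2", "--pmin", "0.01", "--seed", "7",
            "--out", str(out),
        ])
        assert r.exit_code == 0, r.output
        assert "4 clusters" in r.output
        r = runner.invoke(main, [
            "compare",
            "--annotation", f"ref={sim / 'ref.tsv'}",
            "--annotation", f"derived1={sim / 'derived1.tsv'}",
            "--query", str(sim / "query.txt"),
            "--homology", str(sim / "homology.tsv"),
            "--ref-species", "ref",
            "--out", str(out),
        ])
        assert r.exit_code == 0, r.output
        assert "Score(ref, derived1) = 1.0000" in r.output
        r = runner.invoke(main, [
            "circos",
            "--clusters", str(out / "ref" / "clusters.tsv"),
            "--annotation", str(sim / "ref.tsv"),
            "--out", str(tmp_path / "circos"),
        ])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "circos" / "karyotype.txt").exists()
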