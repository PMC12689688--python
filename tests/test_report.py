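"""Pipeline orchestration: reports, thresholds, exports, determinism."""

import json

import numpy as np
import pytest

from kgvet.config import RunConfig
from kgvet.report import (
    apply_thresholds,
    export_report,
    load_report,
    validate_corpus,
)


class TestValidateCorpus:
    def test_shape_contract(self, bundle, report):
        assert len(report.per_triple) == len(bundle.triples)
        assert set(report.summaries) == {"semantic", "type", "resource"}
        ids = [ts.triple_id for ts in report.per_triple]
        assert ids == [t.triple_id for t in bundle.triples]

    def test_planted_unmatched_entities_are_the_flagged_set(self, bundle, report):
        flagged = {ts.triple_id for ts in report.per_triple if ts.resource.flagged}
        assert flagged == bundle.unmatched_ids

    def test_empty_corpus_rejected(self, bundle):
        from kgvet.triples import TripleSet
        with pytest.raises(ValueError):
            validate_corpus(TripleSet([]), bundle.ontology, bundle.backend())

    def test_config_snapshot_embedded(self, report):
        snap = report.config_snapshot
        assert snap["resource"]["damping"] == 0.85
        assert snap["thresholds"] == {"semantic": 0.75, "type": 0.75, "resource": 0.75}

    def test_embed_failure_is_fatal_even_with_keep_going(self, bundle):
        backend = bundle.backend()

        class Flaky(type(backend)):
            def embed(self, text):
                if text == bundle.triples[0].head:
                    raise ValueError("boom")
                return super().embed(text)

        flaky = Flaky(backend.table)
        # the semantic pass is corpus-coupled (shared min-max), so an embed
        # failure is fatal even under keep_going
        with pytest.raises(ValueError):
            validate_corpus(bundle.triples, bundle.ontology, flaky, keep_going=True)


class TestThresholds:
    def test_conjunctive_rule_on_mixed_scores(self, bundle, report):
        decisions = apply_thresholds(report, {"semantic": 0.75, "type": 0.75,
                                              "resource": 0.75})
        assert set(decisions) == {ts.triple_id for ts in report.per_triple}
        for ts in report.per_triple:
            want = (not ts.resource.flagged
                    and ts.semantic.score >= 0.75
                    and ts.type.score >= 0.75
                    and ts.resource.score >= 0.75)
            assert (decisions[ts.triple_id] == "accept") == want

    def test_zero_thresholds_accept_all_nonflagged(self, bundle, report):
        decisions = apply_thresholds(report, {c: 0.0 for c in ("semantic", "type", "resource")})
        rejected = {t for t, d in decisions.items() if d == "reject"}
        assert rejected == bundle.unmatched_ids

    def test_single_low_component_rejects(self, report):
        # a triple passing two views at 0.9 but one at 0.5 must be rejected
        ts = report.per_triple[0]
        fake = apply_thresholds(report, {"semantic": 0.0, "type": 0.0,
                                         "resource": ts.resource.score + 1e-9})
        assert fake[ts.triple_id] == "reject"

    def test_out_of_range_threshold_rejected(self, report):
        with pytest.raises(ValueError):
            apply_thresholds(report, {"semantic": 1.5})

    def test_monotone_in_threshold(self, report):
        sizes = []
        for th in np.linspace(0, 1, 10):
            decisions = apply_thresholds(report, {c: th for c in ("semantic", "type", "resource")})
            sizes.append(sum(1 for d in decisions.values() if d == "accept"))
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_partition_sums_to_corpus_size(self, report):
        decisions = apply_thresholds(report)
        assert len(decisions) == len(report.per_triple)


class TestExport:
    def test_json_round_trip_and_self_consistency(self, report, tmp_path):
        p = tmp_path / "r.json"
        export_report(report, p, "json")
        doc = load_report(p)
        assert doc["schema_version"] == 1
        assert len(doc["per_triple"]) == len(report.per_triple)
        for c in ("semantic", "type", "resource"):
            got = doc["summaries"][c]["mean"]
            scores = [rec[c]["score"] for rec in doc["per_triple"]]
            if c == "resource":  # flagged triples excluded from the mean
                scores = [rec[c]["score"] for rec in doc["per_triple"]
                          if not rec["resource"]["flagged"]]
            assert got == pytest.approx(np.mean(scores), abs=1e-12)

    def test_two_runs_identical_seed_byte_identical_reports(self, bundle, tmp_path):
        paths = []
        for i in (1, 2):
            rep = validate_corpus(bundle.triples, bundle.ontology, bundle.backend())
            p = tmp_path / f"run{i}.json"
            export_report(rep, p, "json")
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_csv_row_count_is_corpus_size_plus_header(self, report, tmp_path):
        p = tmp_path / "r.csv"
        export_report(report, p, "csv")
        lines = p.read_text().strip().splitlines()
        assert len(lines) == len(report.per_triple) + 1

    def test_histogram_bins_conserve_corpus_size(self, report, tmp_path):
        p = tmp_path / "r.json"
        export_report(report, p, "json")
        doc = load_report(p)
        for c, counts in doc["histograms"].items():
            assert len(counts) == 20
            assert sum(counts) == len(report.per_triple)

    def test_tampered_summary_fails_consistency_check(self, bundle, tmp_path):
        from kgvet.stats import ScoreSummary
        rep = validate_corpus(bundle.triples, bundle.ontology, bundle.backend())
        s = rep.summaries["semantic"]
        rep.summaries["semantic"] = ScoreSummary(s.mean + 0.01, s.sd, s.min, s.max, s.n)
        with pytest.raises(ValueError, match="self-consistency"):
            export_report(rep, tmp_path / "bad.json", "json")


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        import yaml
        cfg = RunConfig()
        p = tmp_path / "cfg.yaml"
        p.write_text(yaml.safe_dump(cfg.to_dict()))
        assert RunConfig.from_yaml(p) == cfg

    def test_population_sd_config(self, bundle):
        rep = validate_corpus(bundle.triples, bundle.ontology, bundle.backend(),
                              RunConfig(sd_ddof=0))
        scores = [ts.semantic.score for ts in rep.per_triple]
        assert rep.summaries["semantic"].sd == pytest.approx(np.std(scores))

    def test_per_concept_normalization_changes_scores(self, bundle):
        base = validate_corpus(bundle.triples, bundle.ontology, bundle.backend())
        per = validate_corpus(bundle.triples, bundle.ontology, bundle.backend(),
                              RunConfig(per_concept_normalization=True))
        a = [ts.semantic.score for ts in base.per_triple]
        b = [ts.semantic.score for ts in per.per_triple]
        assert not np.allclose(a, b)
        # raw distances are normalization-independent
        assert [ts.semantic.raw_distance for ts in base.per_triple] == \
               [ts.semantic.raw_distance for ts in per.per_triple]

    def test_weighted_average_rule_accepts_superset(self, bundle):
        conj = validate_corpus(bundle.triples, bundle.ontology, bundle.backend())
        avg = validate_corpus(bundle.triples, bundle.ontology, bundle.backend(),
                              RunConfig(combination_rule="weighted_average"))
        assert set(conj.accepted_ids) <= set(avg.accepted_ids)
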