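"""candidate_prediction: unknown-family selection, filters, pipeline driver."""

import dataclasses

import pytest

from trscout.features import FamilyFeatureSummary
from trscout.io import AnnotationSet
from trscout.predict import (
    PipelineConfig,
    apply_feature_filters,
    run_pipeline,
    select_unknown_families,
    venn_region_counts,
)
from trscout import simulate


def summary(fam, nuclear=0.67, disorder=0.40, autoact=True, size=3, n_disorder=None):
    return FamilyFeatureSummary(
        family_id=fam,
        size=size,
        nuclear_fraction=nuclear,
        mean_disorder=disorder,
        n_members_with_disorder=size if n_disorder is None else n_disorder,
        has_autoactivator=autoact,
        n_members_tested=size,
    )


def annotations_from(mapping, seen_extra=()):
    ann = AnnotationSet()
    for pid, terms in mapping.items():
        ann.seen_ids.add(pid)
        for t in terms:
            ann.add(pid, t)
    ann.seen_ids |= set(seen_extra)
    return ann


class TestSelectUnknownFamilies:
    FAMILIES = {
        "known": {"k1", "k2", "k3"},
        "root_only": {"u1", "u2", "u3"},
        "small": {"s1", "s2"},
    }

    ANN = annotations_from(
        {"k1": {"GO:0003700"}, "u1": {"GO:0003674"}},
        seen_extra=["u2", "s1"],
    )

    def test_one_annotated_member_excludes_family(self):
        unknown, _ = select_unknown_families(self.FAMILIES, self.ANN)
        assert "known" not in unknown

    def test_root_and_missing_annotations_are_unknown(self):
        unknown, filtered = select_unknown_families(self.FAMILIES, self.ANN)
        assert "root_only" in unknown and "root_only" in filtered

    def test_two_member_family_cut_by_size_filter(self):
        unknown, filtered = select_unknown_families(self.FAMILIES, self.ANN)
        assert "small" in unknown and "small" not in filtered

    def test_singleton_mode_admits_small_families(self):
        config = PipelineConfig(singleton_mode=True)
        _, filtered = select_unknown_families(self.FAMILIES, self.ANN, config)
        assert "small" in filtered

    def test_non_mf_aspects_do_not_matter(self):
        # aspect-P/C terms never enter AnnotationSet.mf_terms; a seen-only
        # protein stays unknown
        ann = annotations_from({}, seen_extra=["u1", "u2", "u3"])
        unknown, _ = select_unknown_families({"f": {"u1", "u2", "u3"}}, ann)
        assert unknown == {"f"}


class TestApplyFeatureFilters:
    def test_all_three_criteria_pass(self):
        cands, _ = apply_feature_filters({"f"}, {"f": summary("f")})
        assert cands == {"f"}

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"nuclear": 0.5},  # strict >: exactly 50% nuclear fails
            {"disorder": 0.341},  # strict >: exactly the cutoff fails
            {"autoact": False},
            {"disorder": None, "n_disorder": 0},  # no prediction coverage
        ],
    )
    def test_boundary_and_missing_failures(self, kwargs):
        cands, _ = apply_feature_filters({"f"}, {"f": summary("f", **kwargs)})
        assert cands == set()

    def test_pass_sets_returned_per_filter(self):
        summaries = {
            "n_only": summary("n_only", disorder=0.1, autoact=False),
            "all": summary("all"),
        }
        cands, pass_sets = apply_feature_filters(set(summaries), summaries)
        assert cands == {"all"}
        assert pass_sets["nuclear"] == {"n_only", "all"}
        assert pass_sets["disorder"] == pass_sets["autoactivation"] == {"all"}

    def test_missing_summary_is_error(self):
        with pytest.raises(ValueError):
            apply_feature_filters({"f", "g"}, {"f": summary("f")})

    def test_raising_threshold_never_grows_candidates(self):
        summaries = {
            f"f{i}": summary(f"f{i}", nuclear=0.2 + 0.1 * i, disorder=0.1 + 0.08 * i)
            for i in range(9)
        }
        universe = set(summaries)
        previous = None
        for cut in (0.3, 0.45, 0.6, 0.75):
            config = PipelineConfig(nuclear_fraction_gt=cut)
            cands, _ = apply_feature_filters(universe, summaries, config)
            if previous is not None:
                assert cands <= previous
            previous = cands


class TestVennCounts:
    def test_regions_partition_the_universe(self):
        universe = {f"f{i}" for i in range(10)}
        pass_sets = {
            "nuclear": {"f0", "f1", "f2", "f3"},
            "disorder": {"f2", "f3", "f4"},
            "autoactivation": {"f3", "f4", "f5"},
        }
        counts = venn_region_counts(universe, pass_sets)
        assert sum(counts.values()) == len(universe)
        assert counts["111"] == 1  # f3
        assert counts["011"] == 1  # f4
        assert counts["000"] == 4  # f6..f9
        # intersection never exceeds any single-filter pass set
        assert counts["111"] <= min(len(s) for s in pass_sets.values())


class TestRunPipeline:
    def test_no_planted_regulators_yields_no_candidates(self):
        params = simulate.SimulationParams(seed=5, n_families=40, fraction_planted=0.0)
        bundle = simulate.generate_bundle(params)
        result = run_pipeline(
            bundle.proteome, bundle.graph, bundle.annotations, bundle.features
        )
        assert result.candidates == []
        assert bundle.planted_candidate_ids == set()

    def test_stage_counts_monotone_and_venn_consistent(self):
        bundle = simulate.generate_bundle(simulate.SimulationParams(seed=9, n_families=60))
        result = run_pipeline(
            bundle.proteome, bundle.graph, bundle.annotations, bundle.features
        )
        c = result.stage_counts
        assert c["families_total"] >= c["unknown"] >= c["unknown_size_filtered"]
        assert c["candidates"] <= min(
            c["pass_nuclear"], c["pass_disorder"], c["pass_autoactivation"]
        )
        assert sum(result.venn_counts.values()) == c["unknown_size_filtered"]

    def test_precomputed_families_bypass_clustering(self):
        bundle = simulate.generate_bundle(simulate.SimulationParams(seed=9, n_families=60))
        result = run_pipeline(
            bundle.proteome,
            bundle.graph,
            bundle.annotations,
            bundle.features,
            families=bundle.true_families,
        )
        predicted = {frozenset(result.families[f]) for f in result.candidates}
        expected = {
            frozenset(bundle.true_families[f]) for f in bundle.planted_candidate_ids
        }
        assert predicted == expected

    def test_protein_missing_from_graph_becomes_singleton(self):
        bundle = simulate.generate_bundle(simulate.SimulationParams(seed=9, n_families=30))
        graph = bundle.graph.copy()
        lonely = sorted(bundle.proteome)[0]
        graph.remove_node(lonely)
        result = run_pipeline(bundle.proteome, graph, bundle.annotations, bundle.features)
        assert {lonely} in [set(m) for m in result.families.values()]

    def test_rerun_is_byte_identical(self, tmp_path):
        bundle = simulate.generate_bundle(simulate.SimulationParams(seed=3, n_families=40))
        paths = []
        for name in ("a.json", "b.json"):
            result = run_pipeline(
                bundle.proteome, bundle.graph, bundle.annotations, bundle.features
            )
            out = tmp_path / name
            result.to_json(out)
            paths.append(out)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_result_json_round_trip(self, tmp_path):
        bundle = simulate.generate_bundle(simulate.SimulationParams(seed=3, n_families=40))
        result = run_pipeline(
            bundle.proteome, bundle.graph, bundle.annotations, bundle.features
        )
        out = tmp_path / "r.json"
        result.to_json(out)
        back = type(result).from_json(out)
        assert back.candidates == result.candidates
        assert back.families == result.families
        assert back.config == result.config


class TestPipelineConfig:
    def test_yaml_round_trip(self, tmp_path):
        config = PipelineConfig(min_family_size=4, singleton_mode=False)
        path = tmp_path / "cfg.yaml"
        config.to_yaml(path)
        assert PipelineConfig.from_yaml(path) == config

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            PipelineConfig(nuclear_fraction_gt=1.5)
        with pytest.raises(ValueError):
            PipelineConfig(min_family_size=0)
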