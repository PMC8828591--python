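from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from annogap.audit import (
    AvailabilityPolicy,
    Classification,
    audit_corpus,
    available_before,
    classify_query,
    write_report_json,
    write_results_tsv,
)
from annogap.clustering import ClusterSet, build_cluster_set
from annogap.corpus import Rank, RANKS
from annogap.simulate import SimConfig, generate_corpus
from .conftest import make_record
from .oracles import oracle_classify_pairwise

GENUS_LIN = "Fungi;Basidiomycota;Agaricomycetes;Agaricales;Amanitaceae;Amanita;"
PHYLUM_LIN = "Fungi;Basidiomycota;;;;;"


class TestAvailabilityPolicy:
    def test_exactly_seven_days_is_available(self):
        q = make_record("Q", date="2010-01-10")
        r = make_record("R", date="2010-01-03")
        assert available_before([q, r], q, AvailabilityPolicy()) == {"R"}

    def test_six_days_is_not_available(self):
        q = make_record("Q", date="2010-01-10")
        r = make_record("R", date="2010-01-04")
        assert available_before([q, r], q, AvailabilityPolicy()) == set()

    def test_same_date_excluded(self):
        q = make_record("Q", date="2010-01-10")
        r = make_record("R", date="2010-01-10")
        assert available_before([q, r], q, AvailabilityPolicy()) == set()

    def test_query_never_available_to_itself(self):
        q = make_record("Q", date="2010-01-10")
        assert available_before([q], q, AvailabilityPolicy(lag_days=0)) == set()

    def test_lag_zero_includes_same_day(self):
        q = make_record("Q", date="2010-01-10")
        r = make_record("R", date="2010-01-10")
        assert available_before([q, r], q, AvailabilityPolicy(lag_days=0)) == {"R"}

    def test_negative_lag_rejected(self):
        with pytest.raises(ValueError):
            AvailabilityPolicy(lag_days=-1)

    @pytest.mark.parametrize("lag_a,lag_b", [(0, 7), (7, 30), (0, 365)])
    def test_monotone_in_lag(self, lag_a, lag_b):
        rng = np.random.default_rng(0)
        records = [
            make_record(f"R{i}", date=f"2010-{1 + int(rng.integers(0, 12)):02d}-"
                                       f"{1 + int(rng.integers(0, 28)):02d}")
            for i in range(20)
        ]
        q = make_record("Q", date="2010-06-15")
        small = available_before(records, q, AvailabilityPolicy(lag_days=lag_b))
        large = available_before(records, q, AvailabilityPolicy(lag_days=lag_a))
        assert small <= large


def _manual_clusters() -> tuple[list, ClusterSet]:
    """Hand-built 10-record corpus with one TP, one FN_CLOSE, one FN_REASONABLE."""
    records = [
        # CC0 / SH0: query with a genus-annotated available co-member -> FN_CLOSE
        make_record("Q_CLOSE", date="2010-06-01"),
        make_record("R_GENUS", date="2010-01-01", lineage=GENUS_LIN),
        # CC1: query alone in its SH; phylum-annotated co-member in the
        # compound cluster -> FN_REASONABLE
        make_record("Q_REASON", date="2012-03-15"),
        make_record("R_PHYLUM", date="2011-01-01", lineage=PHYLUM_LIN),
        # CC2: co-members too recent or kingdom-only -> TP
        make_record("Q_TP", date="2010-01-10"),
        make_record("R_LATE", date="2010-01-08", lineage=GENUS_LIN),  # only 2 days older
        make_record("R_KING", date="2005-01-01"),  # old but kingdom-only
        # CC3: annotated non-query fillers
        make_record("F1", date="2009-01-01", lineage=GENUS_LIN),
        make_record("F2", date="2009-02-01", lineage=PHYLUM_LIN),
        make_record("F3", date="2009-03-01", lineage=GENUS_LIN),
    ]
    clusters = ClusterSet(
        compound_members={
            "CC00000": ["Q_CLOSE", "R_GENUS"],
            "CC00001": ["Q_REASON", "R_PHYLUM"],
            "CC00002": ["Q_TP", "R_LATE", "R_KING"],
            "CC00003": ["F1", "F2", "F3"],
        },
        sh_members={
            "CC00000.SH000": ["Q_CLOSE", "R_GENUS"],
            "CC00001.SH000": ["Q_REASON"],
            "CC00001.SH001": ["R_PHYLUM"],
            "CC00002.SH000": ["Q_TP", "R_LATE", "R_KING"],
            "CC00003.SH000": ["F1", "F2", "F3"],
        },
    )
    return records, clusters


class TestClassifyQuery:
    def setup_method(self):
        self.records, self.clusters = _manual_clusters()
        self.by_acc = {r.accession: r for r in self.records}
        self.policy = AvailabilityPolicy()

    def _classify(self, acc):
        return classify_query(self.by_acc[acc], self.by_acc, self.clusters, self.policy)

    def test_fn_close_with_rank_flags(self):
        res = self._classify("Q_CLOSE")
        assert res.classification is Classification.FN_CLOSE
        for rank in (Rank.KINGDOM, Rank.PHYLUM, Rank.CLASS, Rank.ORDER,
                     Rank.FAMILY, Rank.GENUS):
            assert res.rank_available_close[rank]
        assert not res.rank_available_close[Rank.SPECIES]
        assert res.n_available_sh == 1

    def test_fn_reasonable_when_sh_is_singleton(self):
        res = self._classify("Q_REASON")
        assert res.classification is Classification.FN_REASONABLE
        assert res.n_available_sh == 0
        assert res.hitlist_close_props is None
        assert res.rank_available_reasonable[Rank.PHYLUM]
        assert res.hitlist_reasonable_props[Rank.PHYLUM] == 1.0

    def test_tp_when_no_qualifying_match(self):
        res = self._classify("Q_TP")
        assert res.classification is Classification.TP
        # The kingdom-only co-member is available but carries no deeper name.
        assert res.n_available_sh == 1
        assert res.hitlist_close_props[Rank.PHYLUM] == 0.0

    def test_non_kingdom_query_rejected(self):
        with pytest.raises(ValueError):
            classify_query(self.by_acc["R_GENUS"], self.by_acc, self.clusters, self.policy)

    def test_hitlist_props_antitone_in_rank(self):
        for acc in ("Q_CLOSE", "Q_REASON", "Q_TP"):
            res = self._classify(acc)
            for props in (res.hitlist_close_props, res.hitlist_reasonable_props):
                if props is None:
                    continue
                values = [props[r] for r in RANKS if r >= Rank.PHYLUM]
                assert values == sorted(values, reverse=True)


class TestAuditCorpus:
    def test_hand_built_fixture_fractions(self):
        records, clusters = _manual_clusters()
        report, results = audit_corpus(records, clusters)
        assert report.n_queries == 4  # 3 designed queries + kingdom-only R_KING
        by_acc = {r.accession: r.classification for r in results}
        assert by_acc["Q_CLOSE"] is Classification.FN_CLOSE
        assert by_acc["Q_REASON"] is Classification.FN_REASONABLE
        assert by_acc["Q_TP"] is Classification.TP
        assert sum(report.fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_zero_annotated_corpus_all_tp(self):
        records = [make_record(f"K{i}", date=f"20{10 + i}-01-01") for i in range(4)]
        clusters = ClusterSet(
            compound_members={"CC00000": [r.accession for r in records]},
            sh_members={"CC00000.SH000": [r.accession for r in records]},
        )
        report, results = audit_corpus(records, clusters)
        assert report.counts["TP"] == 4
        assert report.fractions["TP"] == 1.0

    def test_no_kingdom_queries_absent_aggregates(self):
        records = [
            make_record("A1", date="2010-01-01", lineage=GENUS_LIN),
            make_record("A2", date="2011-01-01", lineage=PHYLUM_LIN),
        ]
        clusters = ClusterSet(
            compound_members={"CC00000": ["A1", "A2"]},
            sh_members={"CC00000.SH000": ["A1"], "CC00000.SH001": ["A2"]},
        )
        report, results = audit_corpus(records, clusters)
        assert report.n_queries == 0
        assert results == []
        assert report.fractions["TP"] is None
        assert report.median_sh_size_excl_query is None
        assert all(v is None for v in report.rank_availability_close.values())

    def test_fn_close_implies_fn_in_cumulative_reading(self):
        records, clusters = _manual_clusters()
        report, _ = audit_corpus(records, clusters)
        fn_close = report.fractions["FN_CLOSE"]
        fn_total = fn_close + report.fractions["FN_REASONABLE"]
        assert fn_close <= fn_total <= 1.0

    def test_phylum_conflict_rates(self):
        records, clusters = _manual_clusters()
        records.append(make_record("F4", date="2009-04-01",
                                   lineage="Fungi;Ascomycota;;;;;"))
        clusters = ClusterSet(
            compound_members={**clusters.compound_members,
                              "CC00003": ["F1", "F2", "F3", "F4"]},
            sh_members={**clusters.sh_members,
                        "CC00003.SH000": ["F1", "F2", "F3", "F4"]},
        )
        report, _ = audit_corpus(records, clusters)
        # F1..F3 are Basidiomycota, F4 Ascomycota: one conflicted SH and CC.
        assert report.phylum_conflict_rate_sh == pytest.approx(1 / 5)
        assert report.phylum_conflict_rate_cc == pytest.approx(1 / 4)

    def test_output_writers(self, tmp_path):
        records, clusters = _manual_clusters()
        report, results = audit_corpus(records, clusters)
        write_results_tsv(results, tmp_path / "results.tsv")
        write_report_json(report, tmp_path / "report.json")
        lines = (tmp_path / "results.tsv").read_text().splitlines()
        assert len(lines) == 1 + report.n_queries
        assert lines[0].startswith("accession\tclassification\t")


class TestOracleEquivalence:
    def test_pipeline_matches_pairwise_oracle_on_seeded_corpus(self):
        # ~50 records; guards guarantee intra-SH identity >= 97% and
        # cross-compound identity < 80%, where the SH/compound mimicry and a
        # direct pairwise-identity BLAST stand-in must agree exactly.
        config = SimConfig(seed=123, n_families=3, genera_per_family=2,
                           species_per_genus=2, seqs_per_species=4,
                           seq_length=300, p_kingdom_mask=0.45)
        records, _ = generate_corpus(config)
        assert len(records) == 48
        clusters = build_cluster_set(records)
        _, results = audit_corpus(records, clusters)
        pipeline = {r.accession: r.classification.value for r in results}

        from annogap.clustering import global_identity

        expected = oracle_classify_pairwise(records, global_identity)
        assert pipeline == expected
        assert len(expected) > 10
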