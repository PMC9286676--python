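"""Consensus target-gene filter: validation, criteria, oracle agreement."""

import numpy as np
import pandas as pd
import pytest

import hippocoupling as hc
from hippocoupling.consensus import EvidenceFormatError, validate_evidence


def ev(gene, source, study, direction="up", binding="none"):
    return dict(gene=gene, source_type=source, study_id=study,
                direction=direction, binding=binding)


def chip(gene, receptor):
    return ev(gene, "chipseq", f"chipseq_{receptor}", direction="na", binding=receptor)


def make_table(rows):
    return pd.DataFrame(rows, columns=["gene", "source_type", "study_id", "direction", "binding"])


# ---------------------------------------------------------------------------
# brute-force per-gene criterion oracle, independent of apply_consensus

def oracle_calls(table, min_studies=3, require_inhouse=True):
    out = []
    for gene in sorted(set(table["gene"])):
        rows = table[table["gene"] == gene]
        trans = rows[rows["source_type"].isin(["meta_transcriptomic", "inhouse_rnaseq"])]
        c1 = (rows["source_type"] == "meta_transcriptomic").any()
        c2 = (rows["source_type"] == "inhouse_rnaseq").any() or not require_inhouse
        c3 = len(trans) > 0 and trans["direction"].nunique() == 1
        chips = set(rows.loc[rows["source_type"] == "chipseq", "binding"])
        c4 = len(chips) > 0
        c5 = trans["study_id"].nunique() >= min_studies
        if c1 and c2 and c3 and c4 and c5:
            out.append(gene)
    return out


# ---------------------------------------------------------------------------

def test_read_evidence_valid_and_invalid(tmp_path):
    rows = [
        ev("Fkbp5", "meta_transcriptomic", "meta01"),
        ev("Fkbp5", "meta_transcriptomic", "meta02"),
        ev("Fkbp5", "inhouse_rnaseq", "inhouse"),
        chip("Fkbp5", "GR"),
        chip("Fkbp5", "MR"),
        ev("Sgk1", "meta_transcriptomic", "meta01", direction="down"),
    ]
    path = tmp_path / "ev.tsv"
    make_table(rows).to_csv(path, sep="\t", index=False)
    table = hc.read_evidence(path)
    assert len(table) == 6

    bad = make_table(rows + [ev("X", "chipseq", "chipseq_GR", direction="na", binding="none")])
    with pytest.raises(EvidenceFormatError, match="binding annotation"):
        validate_evidence(bad)

    dup = make_table(rows + [ev("Fkbp5", "meta_transcriptomic", "meta01")])
    with pytest.raises(EvidenceFormatError, match="duplicate"):
        validate_evidence(dup)

    bad_enum = make_table([ev("X", "meta_transcriptomic", "s1", direction="sideways")])
    with pytest.raises(EvidenceFormatError, match="direction"):
        validate_evidence(bad_enum)


@pytest.mark.parametrize(
    "chip_rows,expected",
    [
        ([("GR",)], "GR"),
        ([("MR",)], "MR"),
        ([("GR",), ("MR",)], "both"),
        ([], "none"),
    ],
)
def test_classify_binding(chip_rows, expected):
    rows = [ev("g", "meta_transcriptomic", "m1")]
    rows += [chip("g", r[0]) for r in chip_rows]
    assert hc.classify_binding("g", make_table(rows)) == expected


def test_direction_consistency():
    t = make_table([
        ev("g", "meta_transcriptomic", "m1", "up"),
        ev("g", "meta_transcriptomic", "m2", "up"),
        ev("g", "inhouse_rnaseq", "ih", "up"),
        ev("h", "meta_transcriptomic", "m1", "up"),
        ev("h", "inhouse_rnaseq", "ih", "down"),
        ev("k", "meta_transcriptomic", "m1", "down"),
        chip("n", "GR"),
    ])
    assert hc.direction_consistent("g", t) == (True, "up")
    assert hc.direction_consistent("h", t) == (False, None)
    assert hc.direction_consistent("k", t) == (True, "down")
    assert hc.direction_consistent("n", t) == (False, None)  # no transcriptomic rows


def test_empty_table_gives_empty_calls_and_zero_summary():
    empty = make_table([])
    calls = hc.apply_consensus(empty)
    assert len(calls) == 0
    summary = hc.summarize_counts(empty, calls)
    assert all(v == 0 for v in summary.values())


def test_five_gene_toy_matches_oracle():
    """One gene passes everything; four decoys fail one criterion each."""
    rows = (
        # passes all four criteria and has 3 reporting studies
        [ev("good", "meta_transcriptomic", "m1"), ev("good", "meta_transcriptomic", "m2"),
         ev("good", "inhouse_rnaseq", "ih"), chip("good", "GR")]
        # no meta rows
        + [ev("d_meta", "inhouse_rnaseq", "ih"), chip("d_meta", "GR")]
        # no in-house row
        + [ev("d_ih", "meta_transcriptomic", "m1"), ev("d_ih", "meta_transcriptomic", "m2"),
           ev("d_ih", "meta_transcriptomic", "m3"), chip("d_ih", "both")]
        # inconsistent direction
        + [ev("d_dir", "meta_transcriptomic", "m1", "up"),
           ev("d_dir", "meta_transcriptomic", "m2", "down"),
           ev("d_dir", "inhouse_rnaseq", "ih", "up"), chip("d_dir", "MR")]
        # no binding
        + [ev("d_bind", "meta_transcriptomic", "m1"), ev("d_bind", "meta_transcriptomic", "m2"),
           ev("d_bind", "inhouse_rnaseq", "ih")]
    )
    table = make_table(rows)
    calls = hc.apply_consensus(table, min_reporting_studies=3)
    assert list(calls["gene"]) == ["good"]
    assert oracle_calls(table, min_studies=3) == ["good"]
    row = calls.iloc[0]
    assert row["binding_class"] == "GR" and row["direction"] == "up"
    assert row["n_reporting_studies"] == 3
    assert row[[c for c in calls.columns if c.startswith("crit_")]].all()


def test_simulated_tables_match_oracle_and_truth():
    rng = np.random.default_rng(2024)
    for _ in range(60):
        cfg = hc.EvidenceSimConfig(
            n_true_targets=int(rng.integers(0, 6)),
            decoys_per_failure_mode=int(rng.integers(1, 3)),
            n_studies_meta=int(rng.integers(4, 18)),
            seed=int(rng.integers(0, 2**31)),
        )
        table, truth = hc.simulate_evidence(cfg)
        if table.empty:
            continue
        calls = hc.apply_consensus(table, min_reporting_studies=1)
        expected = oracle_calls(table, min_studies=1)
        assert list(calls["gene"]) == expected
        assert set(calls["gene"]) == set(truth.loc[truth["label"] == "pass", "gene"])
        # every called gene's evidence rows all agree with the consensus direction
        for _, call in calls.iterrows():
            rows = table[(table["gene"] == call["gene"])
                         & table["source_type"].isin(["meta_transcriptomic", "inhouse_rnaseq"])]
            assert (rows["direction"] == call["direction"]).all()


def test_row_order_invariance():
    table, _ = hc.simulate_evidence(hc.EvidenceSimConfig(n_true_targets=4, seed=9))
    shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
    c1 = hc.apply_consensus(table)
    c2 = hc.apply_consensus(shuffled)
    pd.testing.assert_frame_equal(c1, c2)


def test_relaxing_criteria_never_shrinks_call_set():
    table, _ = hc.simulate_evidence(
        hc.EvidenceSimConfig(n_true_targets=5, decoys_per_failure_mode=2, seed=17)
    )
    strict = set(hc.apply_consensus(table, min_reporting_studies=3)["gene"])
    fewer_studies = set(hc.apply_consensus(table, min_reporting_studies=1)["gene"])
    no_inhouse = set(hc.apply_consensus(table, require_inhouse=False)["gene"])
    assert strict <= fewer_studies
    assert strict <= no_inhouse


def test_summary_counts_hand_tally():
    rows = (
        [ev("a", "meta_transcriptomic", "m1"), ev("a", "meta_transcriptomic", "m2"),
         ev("a", "inhouse_rnaseq", "ih"), chip("a", "GR")]
        + [ev("b", "meta_transcriptomic", "m1", "down"),
           ev("b", "inhouse_rnaseq", "ih", "down"), chip("b", "GR"), chip("b", "MR")]
        + [ev("c", "meta_transcriptomic", "m1", "up"),
           ev("c", "inhouse_rnaseq", "ih", "down")]
        + [chip("d", "MR")]
    )
    table = make_table(rows)
    calls = hc.apply_consensus(table, min_reporting_studies=2)
    summary = hc.summarize_counts(table, calls)
    assert summary["n_union_genes"] == 4
    assert summary["n_binding_gr_only"] == 1      # a
    assert summary["n_binding_mr_only"] == 1      # d
    assert summary["n_binding_both"] == 1         # b
    assert summary["n_meta_reported"] == 3        # a, b, c
    assert summary["n_inhouse_responsive"] == 3   # a, b, c
    assert summary["n_consistent_overlap"] == 2   # a, b (c inconsistent)
    assert summary["n_calls"] == 2
    assert summary["n_calls_up"] == 1 and summary["n_calls_down"] == 1
    assert summary["n_calls_gr_only"] == 1 and summary["n_calls_both"] == 1
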