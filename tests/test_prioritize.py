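"""Prioritisation cascade, symbol cleanup, seed conservation, annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from temponet.bayesnet import StrengthNetwork
from temponet.errors import InvalidInputError
from temponet.io import read_mature_fasta
from temponet.prioritize import (
    annotate_resources,
    build_mirna_records,
    clean_symbols,
    confidence_enrichment,
    confidence_matrix,
    extract_mti,
    normalized_degree_heat,
    recurrence_tables,
    seed_conserved,
    shortlist_cascade,
)


def _net(arcs, timepoint):
    node_types = {}
    rows = []
    for s, t in arcs:
        node_types[s] = "miRNA" if s.startswith("miR") else "mRNA"
        node_types[t] = "miRNA" if t.startswith("miR") else "mRNA"
        rows.append(
            {
                "source": s,
                "source_type": node_types[s],
                "target": t,
                "target_type": node_types[t],
                "strength": 0.9,
                "retained": True,
            }
        )
    cols = ["source", "source_type", "target", "target_type", "strength", "retained"]
    return StrengthNetwork(pd.DataFrame(rows, columns=cols), node_types, timepoint, 10)


def test_extract_mti_aggregates_timepoints_and_filters_direction():
    networks = {
        "24h": _net([("miR-a", "GeneX"), ("GeneX", "miR-a")], "24h"),
        "72h": _net([("miR-a", "GeneX"), ("GeneY", "GeneZ")], "72h"),
    }
    mti = extract_mti(networks)
    assert len(mti) == 1
    row = mti.iloc[0]
    assert row["mirna"] == "miR-a" and row["mrna"] == "GeneX"
    assert row["timepoints"] == "24h,72h" and row["n_timepoints"] == 2


def test_extract_mti_counts_distinct_pairs(rng):
    arcs24 = [(f"miR-{i%4}", f"Gene{i%7}") for i in range(12)]
    arcs72 = [(f"miR-{i%3}", f"Gene{i%5}") for i in range(9)]
    networks = {"24h": _net(arcs24, "24h"), "72h": _net(arcs72, "72h")}
    mti = extract_mti(networks)
    assert len(mti) == len(set(arcs24) | set(arcs72))


def test_clean_symbols_rules_and_idempotence():
    mti = pd.DataFrame(
        {
            "mirna": ["m"] * 5,
            "mrna": ["Cecr6", "LOC102551234", "Gfap", "RGD1311345", "Abc.1"],
            "timepoints": ["24h"] * 5,
            "n_timepoints": [1] * 5,
        }
    )
    cleaned, removed = clean_symbols(mti)
    assert list(cleaned["mrna"]) == ["TMEM121B", "Gfap"]
    assert set(removed["mrna"]) == {"LOC102551234", "RGD1311345", "Abc.1"}
    again, removed2 = clean_symbols(cleaned)
    pd.testing.assert_frame_equal(again, cleaned)
    assert removed2.empty


@pytest.mark.parametrize(
    "rat, human, expected",
    [
        ("UAGCUUAUCAGA", "UAGCUUAUCAGA", True),
        ("UAGCUUAUCAGA", "AAGCUUAUCAGA", True),  # position 1 excluded
        ("UAGCUUAUCAGA", "UAGCUUGUCAGA", False),  # mismatch at position 7
        ("uagcuuaucaga", "TAGCTTATCAGA", True),  # case and U/T unification
    ],
)
def test_seed_conserved_positions(rat, human, expected):
    assert seed_conserved(rat, human) is expected


def test_seed_conserved_symmetric_and_rejects_short():
    assert seed_conserved("UAGCUUAU", "AAGCUUAU") == seed_conserved(
        "AAGCUUAU", "UAGCUUAU"
    )
    with pytest.raises(InvalidInputError):
        seed_conserved("UAGC", "UAGCUUAU")


def test_seed_conservation_on_fixture_sequences(mature_fasta_path):
    """The three constructed non-conserved pairs fail the seed test; the
    constructed conserved pairs pass it."""
    seqs = read_mature_fasta(mature_fasta_path)
    non_conserved = ["miR-496-3p", "miR-21-3p", "miR-361-3p"]
    conserved = ["miR-132-3p", "let-7c-5p", "miR-155-5p"]
    for name in non_conserved:
        assert not seed_conserved(seqs[f"rno-{name}"], seqs[f"hsa-{name}"])
    for name in conserved:
        assert seed_conserved(seqs[f"rno-{name}"], seqs[f"hsa-{name}"])


def _records(rows):
    return pd.DataFrame(
        rows,
        columns=["mirna", "human_id", "seed_conserved", "targets_24h", "targets_DOFS"],
    )


def test_cascade_stage_logic():
    rec = _records(
        [
            ("miR-zero", "hsa-zero", True, 0, 0),
            ("miR-nohuman", None, None, 3, 1),
            ("miR-single", "hsa-single", True, 0, 4),
            ("miR-multi", "hsa-multi", True, 2, 2),
            ("miR-unconserved", "hsa-unc", False, 1, 1),
        ]
    )
    res = shortlist_cascade(rec)
    r = res.records.set_index("mirna")
    assert not r.loc["miR-zero", "stage1_has_targets"]
    assert r.loc["miR-nohuman", "stage1_has_targets"] and not r.loc["miR-nohuman", "stage2_has_human"]
    # targets at a single time-point: passes stages 1-2, fails stage 3
    assert r.loc["miR-single", "stage2_has_human"] and not r.loc["miR-single", "stage3_multi_timepoint"]
    assert r.loc["miR-multi", "stage4_seed_conserved"]
    assert not r.loc["miR-unconserved", "stage4_seed_conserved"]
    assert res.stage_counts == {
        "universe": 5,
        "stage1_has_targets": 4,
        "stage2_has_human": 3,
        "stage3_multi_timepoint": 2,
        "stage4_seed_conserved": 1,
    }


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.booleans(),
            st.integers(min_value=0, max_value=4),
            st.integers(min_value=0, max_value=4),
            st.sampled_from([None, True, False]),
        ),
        min_size=1,
        max_size=25,
    )
)
def test_cascade_monotone_on_fuzzed_inputs(rows):
    rec = _records(
        [
            (f"m{i}", f"h{i}" if has_h else None, cons, t1, t2)
            for i, (has_h, t1, t2, cons) in enumerate(rows)
        ]
    )
    res = shortlist_cascade(rec).records
    stages = [
        "stage1_has_targets",
        "stage2_has_human",
        "stage3_multi_timepoint",
        "stage4_seed_conserved",
    ]
    for earlier, later in zip(stages, stages[1:]):
        assert (res[later] <= res[earlier]).all()


def test_build_mirna_records_counts_targets_per_timepoint():
    mti = pd.DataFrame(
        {
            "mirna": ["miR-a", "miR-a", "miR-b"],
            "mrna": ["G1", "G2", "G1"],
            "timepoints": ["24h", "24h,DOFS", "DOFS"],
            "n_timepoints": [1, 2, 1],
        }
    )
    rec = build_mirna_records(
        {"miR-a", "miR-b", "miR-c"},
        mti,
        orthology={"miR-a": "hsa-miR-a"},
        timepoints=("24h", "DOFS"),
    ).set_index("mirna")
    assert rec.loc["miR-a", "targets_24h"] == 2
    assert rec.loc["miR-a", "targets_DOFS"] == 1
    assert rec.loc["miR-b", "targets_24h"] == 0
    assert rec.loc["miR-c", ["targets_24h", "targets_DOFS"]].sum() == 0
    # target count at a time-point never exceeds total degree there
    assert rec.loc["miR-a", "targets_24h"] <= 2


def test_recurrence_tables():
    mti = pd.DataFrame(
        {
            "mirna": ["miR-a", "miR-b", "miR-c", "miR-d"],
            "mrna": ["G1", "G1", "G1", "G2"],
            "timepoints": ["24h", "24h", "24h", "72h"],
            "n_timepoints": [1, 1, 1, 1],
        }
    )
    de = pd.DataFrame(
        {
            "entity": ["G1", "G1", "G2"],
            "type": "mRNA",
            "timepoint": ["24h", "72h", "72h"],
            "log2fc": 1.0,
            "p": 0.001,
            "p_adjusted": 0.01,
            "direction": "up",
            "de": True,
        }
    )
    shortlist = {"miR-a", "miR-b", "miR-c", "miR-d"}
    t1, t2 = recurrence_tables(mti, shortlist, de)
    # G1 is DE at two time-points -> its MTIs stay; G2 at one -> excluded
    assert set(t1["mrna"]) == {"G1"}
    assert len(t1) == 3
    assert set(t2["mrna"]) == {"G1"}  # targeted by 3 > 2 shortlist miRNAs
    assert t2.iloc[0]["n_mirnas"] == 3


def test_normalized_degree_heat_two_point_and_constant():
    rec = pd.DataFrame(
        {
            "mirna": ["m1", "m2", "m3"],
            "targets_24h": [1, 2, 0],
            "targets_72h": [3, 2, 0],
            "targets_10d": [0, 2, 5],
        }
    )
    heat, flags = normalized_degree_heat(rec)
    np.testing.assert_allclose(heat.loc["m1", ["24h", "72h"]], [-1.0, 1.0])
    assert np.isnan(heat.loc["m1", "10d"])  # no targets -> missing
    np.testing.assert_allclose(heat.loc["m2"], [0.0, 0.0, 0.0])
    assert flags["m2"]  # constant profile flagged
    assert flags["m3"]  # single defined time-point: non-normalisable


def test_annotate_resources_joins_and_preserves_rows():
    mti = pd.DataFrame(
        {
            "mirna": ["miR-a", "miR-b"],
            "mrna": ["G1", "G2"],
            "timepoints": ["24h", "72h"],
            "n_timepoints": [1, 1],
        }
    )
    prediction = pd.DataFrame(
        {
            "mirna": ["hsa-miR-a", "hsa-miR-a", "bad"],
            "mrna": ["G1", "G9", "G2"],
            "confidence": ["Very High", "Low", "Nonsense"],
        }
    )
    out = annotate_resources(
        mti,
        prediction_table=prediction,
        validated_pairs={("hsa-miR-a", "G1")},
        iclip_pairs=set(),
        human_de_mirnas={"hsa-miR-a"},
        human_de_mrnas={"G2"},
        orthology={"miR-a": "hsa-miR-a"},
    )
    assert len(out) == len(mti)  # attributes only, never rows
    a = out.set_index("mirna")
    assert a.loc["miR-a", "confidence"] == "Very High"
    assert a.loc["miR-b", "confidence"] == "NA"  # absent (malformed row skipped)
    assert bool(a.loc["miR-a", "validated"]) and not bool(a.loc["miR-b", "validated"])
    assert bool(a.loc["miR-a", "human_dysregulated_mirna"])
    assert bool(a.loc["miR-b", "human_dysregulated_mrna"])
    cm = confidence_matrix(out)
    assert cm.loc["G1", "miR-a"] == "Very High"


def test_confidence_enrichment_detects_planted_signal(rng):
    """Network MTIs drawn from high-confidence predictions must show a higher
    Medium+High proportion than the full prediction background."""
    mirnas = [f"hsa-m{i}" for i in range(6)]
    genes = [f"G{i}" for i in range(40)]
    rows = []
    for m in mirnas:
        for g in genes:
            conf = rng.choice(["High", "Medium", "Low"], p=[0.1, 0.2, 0.7])
            rows.append({"mirna": m, "mrna": g, "confidence": conf})
    prediction = pd.DataFrame(rows)
    strong = prediction[prediction["confidence"].isin(["High", "Medium"])].head(25)
    mti = pd.DataFrame(
        {
            "mirna": strong["mirna"].str.replace("hsa-", "", regex=False),
            "mrna": strong["mrna"],
            "timepoints": "24h",
            "n_timepoints": 1,
        }
    )
    annotated = annotate_resources(
        mti,
        prediction_table=prediction,
        orthology={f"m{i}": f"hsa-m{i}" for i in range(6)},
    )
    enr = confidence_enrichment(annotated, prediction)
    assert enr["network"] > enr["background"]
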