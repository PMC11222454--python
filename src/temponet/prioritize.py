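"""miRNA prioritisation and miRNA-mRNA target interaction (MTI) annotation.

From the retained per-time-point networks, direct miRNA->mRNA arcs are
extracted as candidate MTIs. miRNAs are then shortlisted by a filter cascade:

1. drop miRNAs with no inferred mRNA target at any time-point;
2. drop miRNAs without a human orthologue (an input mapping, e.g. rno- to
   hsa- mature miRNA ids);
3. keep miRNAs with inferred targets at two or more time-points;
4. keep miRNAs whose seed region (nucleotides 2-8 of the mature sequence) is
   conserved between the rat and human mature sequences.

MTIs of the shortlisted miRNAs are cross-annotated against external
resources: a predicted-interaction table with confidence classes (Very High /
High / Medium / Low), experimentally validated interaction lists, an
Ago2-iCLIP interaction list, and human-epilepsy differential-expression
lists. Gene symbols are cleaned first: unofficial symbols (containing ".",
or prefixed LOC/RGD) are dropped and a small rat-to-human synonym map is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayesnet import StrengthNetwork
from .errors import InvalidInputError

#: Rat symbols replaced by their human synonyms/orthologues before resource joins.
DEFAULT_SYNONYM_MAP = {"Cecr6": "TMEM121B", "Pnmal2": "PNMA8B", "Oasl2": "OASL"}

CONFIDENCE_CLASSES = ("Very High", "High", "Medium", "Low")

#: 1-based inclusive seed positions within the mature sequence.
SEED_REGION = (2, 8)


def extract_mti(networks: dict[str, StrengthNetwork]) -> pd.DataFrame:
    """One row per distinct (miRNA, mRNA) pair with a retained miRNA->mRNA arc.

    Only direct arcs count; the time-points at which the arc is retained are
    aggregated into the ``timepoints`` column (sorted, comma-joined).
    """
    pair_tps: dict[tuple[str, str], list[str]] = {}
    tp_order = {tp: i for i, tp in enumerate(networks)}
    for tp, net in networks.items():
        arcs = net.retained_arcs()
        mask = (arcs["source_type"] == "miRNA") & (arcs["target_type"] == "mRNA")
        for _, row in arcs[mask].iterrows():
            pair_tps.setdefault((row["source"], row["target"]), []).append(tp)
    rows = [
        {
            "mirna": mirna,
            "mrna": mrna,
            "timepoints": ",".join(sorted(tps, key=tp_order.get)),
            "n_timepoints": len(tps),
        }
        for (mirna, mrna), tps in sorted(pair_tps.items())
    ]
    return pd.DataFrame(rows, columns=["mirna", "mrna", "timepoints", "n_timepoints"])


def clean_symbols(
    mti: pd.DataFrame,
    synonym_map: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop unofficial gene symbols and apply the synonym map.

    Symbols containing ``.`` or beginning with ``LOC`` or ``RGD`` are removed;
    mapped symbols are replaced. Returns (cleaned table, removal log).
    Idempotent: a second application changes nothing.
    """
    synonyms = DEFAULT_SYNONYM_MAP if synonym_map is None else synonym_map
    sym = mti["mrna"].astype(str)
    bad = sym.str.contains(".", regex=False) | sym.str.startswith(("LOC", "RGD"))
    removed = mti.loc[bad].copy()
    removed["reason"] = "unofficial symbol"
    kept = mti.loc[~bad].copy()
    kept["mrna"] = kept["mrna"].map(lambda s: synonyms.get(s, s))
    return kept.reset_index(drop=True), removed.reset_index(drop=True)


def seed_conserved(rat_seq: str, human_seq: str) -> bool:
    """True iff the seed (nt 2-8, 1-based inclusive) is identical rat vs human.

    Case-insensitive, with U and T treated as the same base.
    """
    lo, hi = SEED_REGION
    out = []
    for seq in (rat_seq, human_seq):
        if seq is None or len(seq) < hi:
            raise InvalidInputError(f"sequence too short for seed comparison: {seq!r}")
        out.append(str(seq).upper().replace("U", "T")[lo - 1 : hi])
    return out[0] == out[1]


@dataclass
class CascadeResult:
    """Per-miRNA stage flags plus the per-stage survivor counts."""

    records: pd.DataFrame
    stage_counts: dict[str, int] = field(default_factory=dict)


def build_mirna_records(
    de_mirnas: set[str],
    mti: pd.DataFrame,
    orthology: dict[str, str],
    rat_seqs: dict[str, str] | None = None,
    human_seqs: dict[str, str] | None = None,
    timepoints: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Assemble the per-miRNA table the shortlist cascade consumes.

    ``de_mirnas`` is the universe (all miRNAs DE at any time-point);
    ``orthology`` maps rat ids to human ids; sequences are used for the seed
    conservation flag (left undetermined when either sequence is missing).
    """
    rat_seqs = rat_seqs or {}
    human_seqs = human_seqs or {}
    if timepoints is None:
        tps = sorted({tp for line in mti["timepoints"] for tp in str(line).split(",") if tp})
    else:
        tps = list(timepoints)
    counts: dict[str, dict[str, int]] = {m: {tp: 0 for tp in tps} for m in de_mirnas}
    for _, row in mti.iterrows():
        if row["mirna"] not in counts:
            continue
        for tp in str(row["timepoints"]).split(","):
            if tp in counts[row["mirna"]]:
                counts[row["mirna"]][tp] += 1
    rows = []
    for mirna in sorted(de_mirnas):
        human = orthology.get(mirna)
        conserved: bool | None = None
        if human is not None and mirna in rat_seqs and human in human_seqs:
            conserved = seed_conserved(rat_seqs[mirna], human_seqs[human])
        row = {"mirna": mirna, "human_id": human, "seed_conserved": conserved}
        row.update({f"targets_{tp}": counts[mirna][tp] for tp in tps})
        rows.append(row)
    columns = ["mirna", "human_id", "seed_conserved"] + [f"targets_{tp}" for tp in tps]
    return pd.DataFrame(rows, columns=columns)


def shortlist_cascade(records: pd.DataFrame) -> CascadeResult:
    """Apply the four-stage miRNA shortlist filter; stage k output is a subset
    of stage k-1 output by construction."""
    rec = records.copy()
    tcols = [c for c in rec.columns if c.startswith("targets_")]
    any_targets = rec[tcols].sum(axis=1) > 0 if tcols else pd.Series(False, index=rec.index)
    n_tp_with_targets = (rec[tcols] > 0).sum(axis=1) if tcols else 0

    rec["stage1_has_targets"] = any_targets
    rec["stage2_has_human"] = rec["stage1_has_targets"] & rec["human_id"].notna()
    rec["stage3_multi_timepoint"] = rec["stage2_has_human"] & (n_tp_with_targets >= 2)
    conserved = rec["seed_conserved"].map(lambda v: bool(v) if v is not None and v == v else False)
    rec["stage4_seed_conserved"] = rec["stage3_multi_timepoint"] & conserved
    counts = {
        "universe": len(rec),
        "stage1_has_targets": int(rec["stage1_has_targets"].sum()),
        "stage2_has_human": int(rec["stage2_has_human"].sum()),
        "stage3_multi_timepoint": int(rec["stage3_multi_timepoint"].sum()),
        "stage4_seed_conserved": int(rec["stage4_seed_conserved"].sum()),
    }
    return CascadeResult(records=rec, stage_counts=counts)


def recurrence_tables(
    mti: pd.DataFrame,
    shortlist: set[str],
    de: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recurrently dysregulated targets of the shortlisted miRNAs.

    Table 1: MTIs of shortlist miRNAs whose target mRNA is DE at >= 2
    time-points (the target's DE time-points are recorded). Table 2: per
    time-point, mRNAs targeted by more than 2 shortlist miRNAs, with counts.
    """
    de_mrna = de[(de["type"] == "mRNA") & de["de"]]
    de_tp_count = de_mrna.groupby("entity")["timepoint"].nunique()
    recurrent = set(de_tp_count[de_tp_count >= 2].index)

    sub = mti[mti["mirna"].isin(shortlist)].copy()
    table1 = sub[sub["mrna"].isin(recurrent)].copy()
    table1["target_de_timepoints"] = table1["mrna"].map(
        lambda g: ",".join(sorted(de_mrna.loc[de_mrna["entity"] == g, "timepoint"].unique()))
    )
    table1 = table1.reset_index(drop=True)

    rows = []
    for _, row in sub.iterrows():
        for tp in str(row["timepoints"]).split(","):
            if tp:
                rows.append({"timepoint": tp, "mrna": row["mrna"], "mirna": row["mirna"]})
    if rows:
        long = pd.DataFrame(rows)
        counted = (
            long.groupby(["timepoint", "mrna"])["mirna"].nunique().reset_index(name="n_mirnas")
        )
        table2 = counted[counted["n_mirnas"] > 2].reset_index(drop=True)
    else:
        table2 = pd.DataFrame(columns=["timepoint", "mrna", "n_mirnas"])
    return table1, table2


def normalized_degree_heat(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-miRNA z-score of target counts across time-points with targets.

    Cells where the miRNA has no inferred target are missing (NaN). Rows with
    fewer than two defined time-points, or a constant count profile, are
    flagged non-normalisable (constant rows normalise to 0).
    """
    tcols = [c for c in records.columns if c.startswith("targets_")]
    counts = records.set_index("mirna")[tcols].astype(float)
    counts.columns = [c.removeprefix("targets_") for c in tcols]
    counts = counts.mask(counts == 0)
    heat = counts.copy()
    flags = pd.Series(False, index=counts.index, name="non_normalisable")
    for mirna, row in counts.iterrows():
        defined = row.dropna()
        if len(defined) < 2:
            flags[mirna] = True
            heat.loc[mirna] = np.nan
            continue
        sd = defined.std(ddof=0)
        if sd == 0:
            flags[mirna] = True
            heat.loc[mirna, defined.index] = 0.0
        else:
            heat.loc[mirna, defined.index] = (defined - defined.mean()) / sd
    return heat, flags


def annotate_resources(
    mti: pd.DataFrame,
    prediction_table: pd.DataFrame | None = None,
    validated_pairs: set[tuple[str, str]] | None = None,
    iclip_pairs: set[tuple[str, str]] | None = None,
    human_de_mirnas: set[str] | None = None,
    human_de_mrnas: set[str] | None = None,
    orthology: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Join MTIs against external resources; adds columns, never rows.

    ``prediction_table`` needs columns (mirna, mrna, confidence); joins are on
    the human miRNA id (via ``orthology``, falling back to the rat id) and the
    gene symbol. Missing pairs get confidence ``NA`` and False flags.
    """
    orthology = orthology or {}
    out = mti.copy()
    out["human_mirna"] = out["mirna"].map(lambda m: orthology.get(m, m))

    conf: dict[tuple[str, str], str] = {}
    if prediction_table is not None:
        for _, row in prediction_table.iterrows():
            c = str(row["confidence"])
            if c not in CONFIDENCE_CLASSES:
                continue  # malformed resource row; skipped
            conf[(str(row["mirna"]), str(row["mrna"]))] = c
    pairs = list(zip(out["human_mirna"], out["mrna"]))
    out["confidence"] = [conf.get(p, "NA") for p in pairs]
    validated = validated_pairs or set()
    iclip = iclip_pairs or set()
    out["validated"] = [p in validated for p in pairs]
    out["iclip"] = [p in iclip for p in pairs]
    out["human_dysregulated_mirna"] = out["human_mirna"].isin(human_de_mirnas or set())
    out["human_dysregulated_mrna"] = out["mrna"].isin(human_de_mrnas or set())
    return out


def confidence_matrix(annotated: pd.DataFrame) -> pd.DataFrame:
    """mRNAs x miRNAs matrix of confidence classes ('' where no MTI)."""
    return annotated.pivot_table(
        index="mrna", columns="mirna", values="confidence", aggfunc="first"
    ).fillna("")


def confidence_enrichment(
    annotated: pd.DataFrame,
    prediction_table: pd.DataFrame,
    classes: tuple[str, ...] = ("Medium", "High"),
) -> dict[str, float]:
    """Proportion of selected confidence classes among network MTIs vs among
    all predictions for the same miRNAs (background)."""
    mirnas = set(annotated["human_mirna"])
    bg = prediction_table[prediction_table["mirna"].isin(mirnas)]
    net_prop = float(annotated["confidence"].isin(classes).mean()) if len(annotated) else 0.0
    bg_prop = float(bg["confidence"].isin(classes).mean()) if len(bg) else 0.0
    return {"network": net_prop, "background": bg_prop}
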