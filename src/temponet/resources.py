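"""Synthetic external resources for end-to-end runs on simulated data.

The prioritisation stage consumes resources that, for real data, come from
public databases: a rat-to-human miRNA orthology map, mature sequences, a
predicted-MTI table with confidence classes, validated / iCLIP interaction
lists, and human-disease differential-expression lists. This module
fabricates internally consistent versions of all of these for a synthetic
scenario, so the full cascade and annotation joins are exercisable without
downloads. Planted miRNA->mRNA edges are enriched in the prediction table
(higher inclusion probability and higher confidence classes), mirroring the
expectation that network-inferred interactions overlap predicted ones more
than chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .prioritize import CONFIDENCE_CLASSES, SEED_REGION
from .simulate import MIRNA, MRNA, RegulatoryScenario

_BASES = np.array(list("ACGU"))


@dataclass
class ResourceBundle:
    """Everything the annotation/prioritisation stage joins against."""

    orthology: dict[str, str]
    rat_seqs: dict[str, str]
    human_seqs: dict[str, str]
    prediction: pd.DataFrame
    validated_pairs: set[tuple[str, str]] = field(default_factory=set)
    iclip_pairs: set[tuple[str, str]] = field(default_factory=set)
    human_de_mirnas: set[str] = field(default_factory=set)
    human_de_mrnas: set[str] = field(default_factory=set)


def _random_seq(rng: np.random.Generator, length: int = 22) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate_outside_seed(rng: np.random.Generator, seq: str) -> str:
    """Human variant with the seed kept intact (position 1 substituted)."""
    s = list(seq)
    s[0] = str(rng.choice([b for b in _BASES if b != s[0]]))
    return "".join(s)


def _mutate_inside_seed(rng: np.random.Generator, seq: str) -> str:
    lo, hi = SEED_REGION
    pos = int(rng.integers(lo - 1, hi))
    s = list(seq)
    s[pos] = str(rng.choice([b for b in _BASES if b != s[pos]]))
    return "".join(s)


def generate_resources(
    scenario: RegulatoryScenario,
    seed: int = 0,
    *,
    frac_orthologue: float = 0.9,
    frac_seed_conserved: float = 0.85,
    planted_prediction_rate: float = 0.8,
    background_prediction_rate: float = 0.15,
    frac_validated: float = 0.3,
    frac_iclip: float = 0.2,
    frac_human_de: float = 0.4,
) -> ResourceBundle:
    """Fabricate resource tables consistent with a planted scenario."""
    rng = np.random.default_rng(seed)
    mirnas = sorted(n for n, t in scenario.nodes.items() if t == MIRNA)
    mrnas = sorted(n for n, t in scenario.nodes.items() if t == MRNA)

    orthology: dict[str, str] = {}
    rat_seqs: dict[str, str] = {}
    human_seqs: dict[str, str] = {}
    for m in mirnas:
        rat_seqs[m] = _random_seq(rng)
        if rng.random() < frac_orthologue:
            human = f"hsa-{m}"
            orthology[m] = human
            if rng.random() < frac_seed_conserved:
                human_seqs[human] = _mutate_outside_seed(rng, rat_seqs[m])
            else:
                human_seqs[human] = _mutate_inside_seed(rng, rat_seqs[m])

    planted = {
        (e.source, e.target)
        for e in scenario.edges
        if scenario.nodes[e.source] == MIRNA and scenario.nodes[e.target] == MRNA
    }
    rows = []
    strong = CONFIDENCE_CLASSES[:2]  # Very High, High
    for m in mirnas:
        human = orthology.get(m)
        if human is None:
            continue
        for g in mrnas:
            is_planted = (m, g) in planted
            rate = planted_prediction_rate if is_planted else background_prediction_rate
            if rng.random() >= rate:
                continue
            if is_planted:
                conf = str(rng.choice(strong)) if rng.random() < 0.7 else str(
                    rng.choice(CONFIDENCE_CLASSES)
                )
            else:
                conf = str(rng.choice(CONFIDENCE_CLASSES, p=[0.05, 0.15, 0.3, 0.5]))
            rows.append({"mirna": human, "mrna": g, "confidence": conf})
    prediction = pd.DataFrame(rows, columns=["mirna", "mrna", "confidence"])

    pred_pairs = list(zip(prediction["mirna"], prediction["mrna"]))
    validated = {p for p in pred_pairs if rng.random() < frac_validated}
    iclip = {p for p in pred_pairs if rng.random() < frac_iclip}
    human_de_mirnas = {h for h in orthology.values() if rng.random() < frac_human_de}
    human_de_mrnas = {g for g in mrnas if rng.random() < frac_human_de}

    return ResourceBundle(
        orthology=orthology,
        rat_seqs=rat_seqs,
        human_seqs=human_seqs,
        prediction=prediction,
        validated_pairs=validated,
        iclip_pairs=iclip,
        human_de_mirnas=human_de_mirnas,
        human_de_mrnas=human_de_mrnas,
    )


def write_mature_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")
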