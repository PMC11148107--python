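"""Synthetic peptide screens and networks with planted ground truth.

The generator emulates the bait-titration design of a limited-proteolysis
interaction screen: a zero-dose control plus six bait amounts
(0.05–4.0 μg), four replicates, log-normal peptide intensities (baseline
log2 ~ N(20, 2)), and a planted subset of responder peptides whose expected
log2 intensity follows an additive four-parameter log-logistic sigmoid of
the dose.  Protected semi-tryptic peptides decrease with dose, exposed
fully tryptic peptides increase, so the protection-direction semantics can
be tested downstream.  Missingness is applied both completely at random and
preferentially at low intensity (logistic in log2 intensity).  Everything
is deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .network import InteractionNetwork
from .report_io import REPORT_COLUMNS, OPTIONAL_COLUMNS

__all__ = [
    "DEFAULT_DOSES",
    "SyntheticTruth",
    "generate_screen",
    "generate_null_screen",
    "generate_module_network",
    "write_truth",
    "write_seed_sets",
]

#: The bait-titration design: zero-dose control plus six amounts (μg).
DEFAULT_DOSES = (0.0, 0.05, 0.1, 0.5, 1.0, 2.0, 4.0)

_AMINO = np.array(list("ACDEFGHILMNPQSTVWY"))  # K/R appended for tryptic ends


@dataclass
class SyntheticTruth:
    """Ground truth of a generated fixture.

    responder_precursors maps precursor id to its planted parameters
    (b, c, d, e on the normalized response scale, delta = signed log2
    effect size, protein, tryptic type).  Every responder belongs to an
    interactor protein; planted e lies within the simulated dose range.
    """

    responder_precursors: dict[str, dict] = field(default_factory=dict)
    interactor_proteins: set[str] = field(default_factory=set)
    module_assignments: dict[str, int] = field(default_factory=dict)


def _random_peptide(rng: np.random.Generator, tryptic: str) -> str:
    length = int(rng.integers(7, 18))
    core = "".join(rng.choice(_AMINO, size=length))
    last = rng.choice(["K", "R"])
    return core + last if tryptic == "FT" else core + rng.choice(_AMINO)


def generate_screen(
    n_proteins: int = 50,
    peptides_per_protein: float = 5.0,
    doses: tuple[float, ...] = DEFAULT_DOSES,
    n_replicates: int = 4,
    responder_fraction: float = 0.1,
    effect_size: float = 2.0,
    noise_sd: float = 0.15,
    missing_rate: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a long-format peptide report with planted dose responders.

    ``peptides_per_protein`` is the Poisson mean of the per-protein peptide
    count (floored at 2 so proteins can survive the two-precursor filter).
    ``responder_fraction`` is applied at the protein level:
    round(fraction * n_proteins) proteins are interactors and each of their
    precursors responds with probability 0.7 (at least one forced).
    Responder curves have slope b ~ U(0.8, 2), EC50 e log-uniform in
    [0.1, 2.0] μg (recoverable within the dose range) and signed log2
    effect ~ ±N(effect_size, 0.25), negative for protected ST peptides and
    positive for exposed FT peptides.
    """
    if not (0.0 <= responder_fraction <= 1.0):
        raise ValueError("responder_fraction must lie in [0, 1]")
    if 0.0 not in doses:
        raise ValueError("doses must include the zero-dose control")
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    rng = np.random.default_rng(seed)
    doses = tuple(float(d) for d in doses)
    truth = SyntheticTruth()
    n_interactors = int(round(responder_fraction * n_proteins))
    interactor_idx = set(
        rng.choice(n_proteins, size=n_interactors, replace=False).tolist()
    ) if n_interactors else set()

    rows = []
    for ip in range(n_proteins):
        protein = f"P{ip + 1:04d}"
        n_pep = max(2, int(rng.poisson(peptides_per_protein)))
        is_interactor = ip in interactor_idx
        responder_flags = (
            rng.random(n_pep) < 0.7 if is_interactor else np.zeros(n_pep, dtype=bool)
        )
        if is_interactor and not responder_flags.any():
            responder_flags[int(rng.integers(n_pep))] = True
        if is_interactor:
            truth.interactor_proteins.add(protein)
        for jp in range(n_pep):
            responds = bool(responder_flags[jp])
            if responds:
                tryptic = "ST" if rng.random() < 0.5 else "FT"
            else:
                tryptic = "ST" if rng.random() < 0.3 else "FT"
            peptide = _random_peptide(rng, tryptic)
            precursor = f"{peptide}/{int(rng.integers(2, 4))}"
            baseline = rng.normal(20.0, 2.0)
            if responds:
                b = float(rng.uniform(0.8, 2.0))
                e = float(np.exp(rng.uniform(np.log(0.1), np.log(2.0))))
                delta = float(np.clip(rng.normal(effect_size, 0.25), 1.0, None))
                if tryptic == "ST":
                    delta = -delta  # protected region: less protease cutting
                truth.responder_precursors[precursor] = {
                    "protein_id": protein,
                    "tryptic_type": tryptic,
                    "b": b,
                    "c": 0.0,
                    "d": 1.0,
                    "e": e,
                    "delta": delta,
                }
            for dose in doses:
                if responds:
                    frac = 0.0 if dose == 0 else dose**b / (dose**b + e**b)
                    mu = baseline + delta * frac
                else:
                    mu = baseline
                for rep in range(1, n_replicates + 1):
                    log2_val = mu + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                    rows.append(
                        (protein, peptide, precursor, dose, rep,
                         float(2.0**log2_val), tryptic, True)
                    )
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS + OPTIONAL_COLUMNS)

    if missing_rate > 0:
        log2_int = np.log2(report["intensity"].to_numpy())
        mcar = rng.random(len(report)) < missing_rate / 2.0
        t0 = np.quantile(log2_int, missing_rate / 2.0)
        p_mnar = 1.0 / (1.0 + np.exp((log2_int - t0) / 0.5))
        mnar = rng.random(len(report)) < p_mnar
        report.loc[mcar | mnar, "intensity"] = np.nan
    return report, truth


def generate_null_screen(
    n_proteins: int = 100,
    peptides_per_protein: float = 5.0,
    doses: tuple[float, ...] = DEFAULT_DOSES,
    n_replicates: int = 4,
    noise_sd: float = 0.15,
    missing_rate: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """A screen with no planted responders (false-positive-rate control)."""
    return generate_screen(
        n_proteins=n_proteins,
        peptides_per_protein=peptides_per_protein,
        doses=doses,
        n_replicates=n_replicates,
        responder_fraction=0.0,
        noise_sd=noise_sd,
        missing_rate=missing_rate,
        seed=seed,
    )


def generate_module_network(
    n_nodes: int = 60,
    n_modules: int = 3,
    p_in: float = 0.6,
    p_out: float = 0.02,
    n_seeds_per_module: int = 5,
    seed: int = 0,
) -> tuple[InteractionNetwork, dict[int, set[str]], SyntheticTruth]:
    """Planted-partition random graph with per-module seed gene sets.

    Nodes split into ``n_modules`` equal communities; edges appear with
    probability ``p_in`` inside and ``p_out`` between communities.  Edge
    confidences are drawn uniformly from [0.75, 1.0].  Returns the network,
    a map module id -> seed set, and the truth with module assignments.
    """
    if not (0.0 <= p_out < p_in <= 1.0):
        raise ValueError("require 0 <= p_out < p_in <= 1")
    size = n_nodes // n_modules
    rng = np.random.default_rng(seed)
    g_raw = nx.planted_partition_graph(
        n_modules, size, p_in, p_out, seed=int(rng.integers(2**31 - 1))
    )
    mapping = {i: f"G{i + 1:04d}" for i in g_raw.nodes}
    g = nx.Graph()
    g.add_nodes_from(mapping.values())
    for a, b in g_raw.edges:
        g.add_edge(mapping[a], mapping[b], weight=float(rng.uniform(0.75, 1.0)))
    truth = SyntheticTruth()
    partition = g_raw.graph["partition"]
    for mod_id, members in enumerate(partition):
        for node in members:
            truth.module_assignments[mapping[node]] = mod_id
    seed_sets: dict[int, set[str]] = {}
    for mod_id, members in enumerate(partition):
        named = sorted(mapping[v] for v in members)
        k = min(n_seeds_per_module, len(named))
        seed_sets[mod_id] = set(rng.choice(named, size=k, replace=False).tolist())
    return InteractionNetwork(g), seed_sets, truth


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Ground-truth TSV: one row per responder precursor."""
    rows = [
        {"precursor_id": prec, **params}
        for prec, params in sorted(truth.responder_precursors.items())
    ]
    cols = ["precursor_id", "protein_id", "tryptic_type", "b", "c", "d", "e", "delta"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_seed_sets(seed_sets: dict[int, set[str]], path: str | Path) -> None:
    rows = [
        {"module": mod, "node": node}
        for mod, nodes in sorted(seed_sets.items())
        for node in sorted(nodes)
    ]
    pd.DataFrame(rows, columns=["module", "node"]).to_csv(path, sep="\t", index=False)
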