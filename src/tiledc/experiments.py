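"""Reproducible simulation experiments exercising the full pipeline.

These drive the synthetic generator through balance -> scale ->
quantification -> group testing and report detection rates, the way a
power analysis of the pipeline would.  Problem sizes are arguments so
the same experiment runs at desk scale or larger.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .domains import ep_contacts, intra_tad_ratio
from .genome import BinGrid, Feature, FeatureSet, GenomicInterval
from .matrix import SampleMeta, ice_balance, scale_to_mean_total
from .simulate import DomainSpec, LoopSpec, SimulationConfig, expected_matrix, sample_counts
from .stats import dunn_test

__all__ = [
    "two_state_subtad_config",
    "subtad_detection_rate",
    "ep_loop_config",
    "ep_lambda_trend_rate",
]


def two_state_subtad_config(
    boost_a: float, boost_b: float, depth: int = 500_000, replicates: int = 4
) -> SimulationConfig:
    """Two conditions identical except for one sub-domain's boost.

    A compact 300-bin tile at 2 kb resolution with a 160-bin main
    domain and a 50-bin sub-domain whose enrichment is ``boost_a`` in
    condition A and ``boost_b`` in condition B.
    """
    grid = BinGrid(GenomicInterval("chrS", 0, 600_000), 2000)
    domains = [
        DomainSpec("main", 60, 220, {"A": 2.0, "B": 2.0}),
        DomainSpec("sub", 120, 170, {"A": boost_a, "B": boost_b}),
    ]
    return SimulationConfig(
        grid=grid,
        decay_exponent=1.0,
        domains=domains,
        loops=[],
        states=["A", "B"],
        replicates_per_state=replicates,
        depth=depth,
        seed=0,
    )


def _per_state_ratios(config: SimulationConfig, domain: DomainSpec, seed: int) -> dict:
    """Balance and scale every replicate, pool per-bin insulation ratios."""
    rng = np.random.default_rng(seed)
    balanced = []
    for state in config.states:
        dense = expected_matrix(config, state)
        for rep in range(config.replicates_per_state):
            rep_seed = int(rng.integers(0, 2**31 - 1))
            m = sample_counts(
                dense, config.depth, rep_seed, config.grid,
                SampleMeta(state=state, replicate=str(rep)),
            )
            b, _ = ice_balance(m)
            balanced.append(b)
    scaled = scale_to_mean_total(balanced)
    groups: dict[str, list[float]] = {s: [] for s in config.states}
    for m in scaled:
        res = intra_tad_ratio(m, range(domain.start, domain.stop))
        groups[m.meta.state].extend(res.ratios.tolist())
    return groups


def subtad_detection_rate(
    boost_a: float,
    boost_b: float,
    n_seeds: int = 20,
    depth: int = 500_000,
    replicates: int = 4,
    alpha: float = 0.05,
    base_seed: int = 0,
) -> tuple[int, list[float]]:
    """How often KW + Dunn (Holm) flags the sub-domain boost difference.

    Returns (number of runs with adjusted p < alpha, the adjusted
    p-values).  With ``boost_a == boost_b`` this measures the false
    positive rate of the full pipeline.
    """
    config = two_state_subtad_config(boost_a, boost_b, depth, replicates)
    domain = config.domain("sub")
    p_values = []
    for i in range(n_seeds):
        groups = _per_state_ratios(config, domain, seed=base_seed + 7919 * i)
        dunn = dunn_test(groups, adjust="holm")
        p_values.append(float(dunn.table["p_adj"].iloc[0]))
    detections = sum(p < alpha for p in p_values)
    return detections, p_values


def ep_loop_config(lam: float, depth: int = 500_000) -> SimulationConfig:
    """Single promoter-enhancer loop of strength ``lam`` on a small tile."""
    grid = BinGrid(GenomicInterval("chrS", 0, 300_000), 2000)  # 150 bins
    promoter_bin, enhancer_bin = 40, 90
    enhancer = Feature(
        "E1", GenomicInterval("chrS", enhancer_bin * 2000, (enhancer_bin + 1) * 2000),
        "enhancer",
    )
    return SimulationConfig(
        grid=grid,
        decay_exponent=1.0,
        domains=[DomainSpec("dom", 20, 110, {"S": 2.0})],
        loops=[LoopSpec("EP", promoter_bin, enhancer_bin, {"S": lam}, width=1.0)],
        states=["S"],
        replicates_per_state=1,
        depth=depth,
        seed=0,
        features=FeatureSet([enhancer]),
    )


def ep_lambda_trend_rate(
    lambdas: tuple[float, ...] = (0.0, 2.0, 5.0),
    n_seeds: int = 20,
    depth: int = 500_000,
    base_seed: int = 0,
) -> tuple[int, list[list[float]]]:
    """How often mean E-P totals increase strictly with loop strength.

    For each seed, one matrix is sampled per lambda at equal depth, the
    promoter's contacts with the enhancer bins are totalled, and the
    seed counts as a success when totals are strictly increasing across
    the lambda series.  Returns (successes, per-seed total lists).
    """
    configs = [ep_loop_config(lam, depth) for lam in lambdas]
    expecteds = [expected_matrix(c, "S") for c in configs]
    promoter_bin = configs[0].loops[0].anchor_a
    totals_per_seed: list[list[float]] = []
    successes = 0
    for i in range(n_seeds):
        rng = np.random.default_rng(base_seed + 104729 * i)
        totals = []
        for cfg, dense in zip(configs, expecteds):
            m = sample_counts(dense, depth, int(rng.integers(0, 2**31 - 1)), cfg.grid)
            b, _ = ice_balance(m)
            res = ep_contacts(b, promoter_bin, cfg.features, cfg.grid)
            totals.append(res.total)
        totals_per_seed.append(totals)
        if all(x < y for x, y in zip(totals, totals[1:])):
            successes += 1
    return successes, totals_per_seed
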