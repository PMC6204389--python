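"""Shared fixtures: the default synthetic dataset run through the pipeline."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

import coexnet as cx


@dataclass
class PipelineRun:
    """Everything the default end-to-end run produces."""

    config: cx.SimConfig
    counts: cx.CountMatrix
    truth: cx.TruthBundle
    filtered: cx.CountMatrix
    factors: pd.Series
    expr: cx.ExprMatrix
    de: cx.DEResult
    log_values: pd.DataFrame
    beta: int
    cor: pd.DataFrame
    tom: np.ndarray
    partition: cx.ModulePartition
    edges: pd.DataFrame
    hubs: cx.HubSet


@pytest.fixture(scope="session")
def pipeline_run() -> PipelineRun:
    """Default study conditions (~1200 genes, 6 planted modules, 12 samples)
    pushed through filtering, TMM/RPKM, DE calling, network construction,
    module detection and hub calling."""
    config = cx.SimConfig(seed=1)
    counts, truth = cx.simulate_expression(config)
    filtered = cx.filter_low_expression(counts)
    factors = cx.tmm_factors(filtered)
    expr = cx.rpkm(filtered, factors)
    de = cx.call_de(expr, filtered.sample_meta, control=config.control_condition)
    log_values = np.log2(expr.values + 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = cx.pick_soft_threshold(log_values)
    cor = cx.correlation_matrix(log_values)
    tom = cx.tom_matrix(cx.signed_adjacency(cor.to_numpy(), fit.chosen_beta))
    partition = cx.cluster_and_cut(tom, gene_ids=list(log_values.index))
    partition = cx.merge_modules(log_values, partition)
    edges = cx.export_edges(cor, partition, beta=fit.chosen_beta)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hubs = cx.find_hubs(edges)
    return PipelineRun(
        config=config, counts=counts, truth=truth, filtered=filtered,
        factors=factors, expr=expr, de=de, log_values=log_values,
        beta=fit.chosen_beta, cor=cor, tom=tom, partition=partition,
        edges=edges, hubs=hubs,
    )


def make_count_matrix(counts, lengths=None, conditions=None) -> cx.CountMatrix:
    """Small helper for hand-built count matrices in unit tests."""
    counts = pd.DataFrame(counts)
    counts.index = [f"g{i}" for i in range(counts.shape[0])]
    counts.columns = [f"s{j}" for j in range(counts.shape[1])]
    if lengths is None:
        lengths = pd.Series(1000, index=counts.index)
    else:
        lengths = pd.Series(lengths, index=counts.index)
    if conditions is None:
        conditions = ["c"] * counts.shape[1]
    meta = pd.DataFrame({
        "condition": conditions,
        "timepoint": [24] * counts.shape[1],
        "replicate": list(range(1, counts.shape[1] + 1)),
    }, index=counts.columns)
    return cx.CountMatrix(counts=counts, gene_lengths=lengths, sample_meta=meta)
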