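"""Artifact writers: solution tables, classification tables, manifests.

Every run directory is self-describing: a ``manifest.json`` captures the
inputs, configuration and seed needed to reproduce it exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from spamscale.classify import agreement_curves, centrality_table, pair_table
from spamscale.proximity import ProximityStack
from spamscale.scaling import ScalingConfig, ScalingProfile, ScalingSolution, weirdness

__all__ = ["write_solution", "write_profile_artifacts", "write_manifest"]

logger = logging.getLogger(__name__)


def write_solution(
    sol: ScalingSolution,
    stack: ProximityStack,
    outdir: str | Path,
    seed: int,
) -> None:
    """Write one dimensionality's coordinates, weights, and summary JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    k = sol.dims
    dim_cols = [f"dim_{a + 1}" for a in range(k)]
    coords = pd.DataFrame(sol.X, columns=dim_cols)
    coords.insert(0, "item_id", stack.items.item_ids)
    coords.to_csv(outdir / f"coordinates_dim{k}.csv", index=False)

    weights = pd.DataFrame(sol.W, columns=dim_cols)
    weights.insert(0, "subject_id", stack.subject_ids)
    if k >= 2:
        weights["weirdness"] = weirdness(sol.W)
    else:
        logger.info(
            "weirdness scores are undefined for one-dimensional solutions; "
            "omitting the weirdness column for dim 1"
        )
    weights.to_csv(outdir / f"weights_dim{k}.csv", index=False)

    summary = {
        "dims": k,
        "stress1": sol.stress1,
        "rsq": sol.rsq,
        "n_iter": sol.n_iter,
        "stop_reason": sol.stop_reason,
        "seed": seed,
        "stress_per_subject": sol.stress_per_subject.tolist(),
    }
    with open(outdir / f"summary_dim{k}.json", "w") as fh:
        json.dump(summary, fh, indent=2)


def write_profile_artifacts(
    prof: ScalingProfile,
    stack: ProximityStack,
    outdir: str | Path,
    cfg: ScalingConfig,
) -> None:
    """Write the full artifact set for a scaled stack.

    Per dimensionality: solution files plus pair and centrality tables
    (one block per dimensionality in a single CSV each); across
    dimensionalities: scree data and all four agreement curves.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pair_blocks, cent_blocks = [], []
    for k in prof.dims:
        sol = prof.solutions[k]
        write_solution(sol, stack, outdir, cfg.seed)
        pt = pair_table(sol, stack.items)
        pt.insert(0, "dimensionality", k)
        pair_blocks.append(pt)
        ct = centrality_table(sol, stack.items)
        ct.insert(0, "dimensionality", k)
        cent_blocks.append(ct)
    pd.concat(pair_blocks).to_csv(outdir / "pair_table.csv", index=False)
    pd.concat(cent_blocks).to_csv(outdir / "centrality_table.csv", index=False)

    scree = pd.DataFrame(
        {
            "dimensionality": prof.dims,
            "stress1": [prof.stress_by_dim[k] for k in prof.dims],
            "rsq": [prof.rsq_by_dim[k] for k in prof.dims],
        }
    )
    scree.to_csv(outdir / "scree.csv", index=False)

    if len(prof.dims) >= 2:
        for basis in ("pairs", "centrality"):
            frames = [
                agreement_curves(prof, mode=mode, basis=basis).to_frame()
                for mode in ("raw", "ordinal")
            ]
            pd.concat(frames).to_csv(outdir / f"agreement_{basis}.csv", index=False)
    else:
        logger.info("agreement curves need at least two dimensionalities; skipped")


def write_manifest(outdir: str | Path, **fields) -> None:
    """Write a reproduction manifest; dataclasses are serialised inline."""
    payload = {}
    for key, value in fields.items():
        if dataclasses.is_dataclass(value) and not isinstance(value, type):
            value = dataclasses.asdict(value)
        payload[key] = value
    with open(Path(outdir) / "manifest.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
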