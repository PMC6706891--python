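"""Tab-delimited table formats shared by the simulator and the CLI.

Counts: rows = species (first column ``species_id``), columns = sample IDs.
Metadata: columns ``sample_id``, ``replicate``, ``time``. Within a replicate,
samples are sorted by time.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("beem")


def read_counts_table(path: str | Path) -> pd.DataFrame:
    """Species x samples count table; duplicate IDs and negative cells are
    rejected with the offending location."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate species ID {dup!r}")
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(f"{path}: missing/ragged cell at species {df.index[r]!r}, "
                         f"sample {df.columns[c]!r} (line {r + 2})")
    vals = df.to_numpy(dtype=float)
    if np.any(vals < 0):
        r, c = np.argwhere(vals < 0)[0]
        raise ValueError(f"{path}: negative value at species {df.index[r]!r}, "
                         f"sample {df.columns[c]!r} (line {r + 2})")
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata mapping every sample to (replicate, time)."""
    meta = pd.read_csv(path, sep="\t")
    required = {"sample_id", "replicate", "time"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    meta["time"] = pd.to_numeric(meta["time"], errors="raise")
    if meta["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample_id")
    if meta.duplicated(subset=["replicate", "time"]).any():
        dup = meta[meta.duplicated(subset=["replicate", "time"])].iloc[0]
        raise ValueError(
            f"{path}: duplicate (replicate, time) = ({dup['replicate']}, {dup['time']})"
        )
    return meta


def assemble_replicates(
    counts: pd.DataFrame, meta: pd.DataFrame
) -> tuple[list[np.ndarray], list[np.ndarray], list[str], list[list[str]]]:
    """Split the flat count table into per-replicate matrices ordered by time.

    Returns (counts_by_rep, times_by_rep, species_ids, sample_ids_by_rep).
    """
    absent = set(counts.columns) - set(meta["sample_id"])
    if absent:
        raise ValueError(f"samples present in counts but absent in metadata: {sorted(absent)[:5]}")
    meta = meta[meta["sample_id"].isin(counts.columns)]
    counts_by_rep, times_by_rep, ids_by_rep = [], [], []
    for _, grp in meta.groupby("replicate", sort=True):
        grp = grp.sort_values("time")
        counts_by_rep.append(counts[grp["sample_id"]].to_numpy(dtype=float))
        times_by_rep.append(grp["time"].to_numpy(dtype=float))
        ids_by_rep.append(grp["sample_id"].tolist())
    return counts_by_rep, times_by_rep, list(counts.index.astype(str)), ids_by_rep


@dataclass
class RunConfig:
    """Echo of every tunable of a CLI run, written to the output directory."""

    subcommand: str
    counts: str | None = None
    metadata: str | None = None
    outdir: str = "."
    max_iter: int = 100
    tol: float = 1e-3
    tau: float = 5.0
    loess_span: float = 0.75
    eq_fraction: float = 0.8
    eq_change: float = 0.05
    min_mean_abundance: float = 0.0
    sparse_mode: str = "ebic"
    reference: int | None = None
    seed: int = 0

    def write(self, outdir: str | Path) -> None:
        Path(outdir, "config.json").write_text(json.dumps(asdict(self), indent=2) + "\n")


def write_fit_outputs(
    outdir: str | Path,
    sample_ids: list[str],
    species_ids: list[str],
    m_hat: np.ndarray,
    mu: np.ndarray,
    beta: np.ndarray,
    a_hat: np.ndarray,
    b_hat: np.ndarray,
    reference_index: int,
    mse_trace: list[float],
    edges: pd.DataFrame,
    warnings: list[str],
) -> dict[str, Path]:
    """Write the standard fit outputs with deterministic column order."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    biomass = pd.DataFrame({"sample_id": sample_ids, "biomass": m_hat})
    paths["biomass"] = outdir / "biomass.tsv"
    biomass.to_csv(paths["biomass"], sep="\t", index=False)

    glv = pd.DataFrame(beta, index=species_ids, columns=species_ids)
    glv.insert(0, "mu", mu)
    glv.index.name = "species_id"
    paths["params_glv"] = outdir / "params_glv.tsv"
    glv.to_csv(paths["params_glv"], sep="\t")

    alr_ids = [s for k, s in enumerate(species_ids) if k != reference_index]
    ab = pd.DataFrame(b_hat, index=alr_ids, columns=species_ids)
    ab.insert(0, "a", a_hat)
    ab.index.name = "species_id"
    paths["params_ab"] = outdir / "params_ab.tsv"
    ab.to_csv(paths["params_ab"], sep="\t")

    trace = pd.DataFrame({"iteration": np.arange(1, len(mse_trace) + 1), "mse": mse_trace})
    paths["trace"] = outdir / "trace.tsv"
    trace.to_csv(paths["trace"], sep="\t", index=False)

    paths["network"] = outdir / "network.tsv"
    edges.to_csv(paths["network"], sep="\t", index=False)

    paths["log"] = outdir / "run.log"
    paths["log"].write_text("".join(w + "\n" for w in warnings))
    return paths
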