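"""Ecological summaries of the final taxon x sample dataset.

Builds the taxon-by-sample abundance matrix from the reassigned MOTU
set, computes analytic (hypergeometric, individual-based) rarefaction
curves, per-taxon occurrence/abundance profiles across depth and
plankton size-fraction strata, and clade composition per size fraction
with an optional side-by-side comparison against user-supplied sediment
counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .readprep import SampleInfo
from .taxon import TaxonPath
from .taxonomy import EcologicalDataset


def build_table(
    dataset: EcologicalDataset, sample_info: Mapping[str, SampleInfo]
) -> pd.DataFrame:
    """Taxon x sample read-count matrix (rows: 4-rank path strings).

    Columns follow the order of ``sample_info``; samples without reads
    keep zero columns so strata stay complete.
    """
    samples = list(sample_info)
    data = {
        taxon.as_string(): [dataset.counts[taxon].get(s, 0) for s in samples]
        for taxon in dataset.taxa
    }
    table = pd.DataFrame.from_dict(data, orient="index", columns=samples)
    return table.astype(int)


def sample_metadata(sample_info: Mapping[str, SampleInfo]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "station": [i.station for i in sample_info.values()],
            "depth": [i.depth for i in sample_info.values()],
            "size_fraction": [i.size_fraction for i in sample_info.values()],
        },
        index=list(sample_info),
    )


def rarefy(counts: Sequence[int] | np.ndarray, depths: Sequence[int] | np.ndarray) -> np.ndarray:
    """Expected taxon richness in random subsamples of the given depths.

    Individual-based analytic rarefaction: for total N reads and per-taxon
    counts N_i,

        E[S_n] = sum_i [1 - C(N - N_i, n) / C(N, n)]

    computed with log-gamma for numerical stability.  Deterministic — no
    resampling.
    """
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    N = int(counts.sum())
    depths = np.asarray(depths, dtype=np.int64)
    if (depths > N).any():
        raise ValueError(f"subsample depth exceeds total reads ({N})")
    if (depths < 0).any():
        raise ValueError("subsample depths must be non-negative")
    out = np.empty(depths.shape, dtype=float)
    for k, n in enumerate(depths):
        if n == 0:
            out[k] = 0.0
            continue
        with np.errstate(invalid="ignore"):
            # log C(N - Ni, n) - log C(N, n); term is 0 when N - Ni < n
            Ni = counts
            ok = (N - Ni) >= n
            log_ratio = (
                gammaln(N - Ni[ok] + 1)
                - gammaln(n + 1)
                - gammaln(N - Ni[ok] - n + 1)
                - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
            )
            out[k] = float(np.sum(1.0 - np.exp(log_ratio)) + np.sum(~ok))
    return out


@dataclass
class RarefactionCurve:
    stratum: str
    depths: np.ndarray
    expected_richness: np.ndarray


def rarefaction_curves(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    by: str | None = None,
    step: int = 100,
) -> list[RarefactionCurve]:
    """Rarefaction per stratum (a metadata column) plus the pooled total.

    ``by=None`` computes only the total curve; otherwise one curve per
    level of the metadata column (e.g. "station", "depth",
    "size_fraction"), reads pooled within the stratum.
    """
    curves: list[RarefactionCurve] = []

    def _curve(name: str, counts: np.ndarray) -> None:
        N = int(counts.sum())
        if N == 0:
            warnings.warn(f"stratum {name!r} has no reads; skipped")
            return
        depths = np.arange(step, N, step, dtype=np.int64)
        depths = np.concatenate([[1], depths, [N]])
        curves.append(
            RarefactionCurve(
                stratum=name,
                depths=depths,
                expected_richness=rarefy(counts, depths),
            )
        )

    _curve("total", table.values.sum(axis=1))
    if by is not None:
        for level, samples in metadata.groupby(by).groups.items():
            _curve(f"{by}={level}", table[list(samples)].values.sum(axis=1))
    return curves


def composition_by_fraction(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    clade_map: Mapping[str, str],
    sediment_counts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Relative read proportion of each clade per sample, grouped by size
    fraction; optionally appended with sediment-count proportions.

    ``clade_map`` maps taxon path strings (table rows) to clade names;
    an unmapped taxon is an error.  ``sediment_counts`` rows are clades,
    single column of counts; they appear as extra rows with
    size_fraction "sediment".
    """
    unmapped = [t for t in table.index if t not in clade_map]
    if unmapped:
        raise ValueError(f"taxa missing from clade map: {unmapped}")
    clades = pd.Series({t: clade_map[t] for t in table.index}, name="clade")
    by_clade = table.groupby(clades).sum()
    props = by_clade / by_clade.sum(axis=0)
    long = props.T
    long["size_fraction"] = metadata.loc[long.index, "size_fraction"]
    if sediment_counts is not None:
        sed = sediment_counts.iloc[:, 0]
        sed_prop = (sed / sed.sum()).to_frame().T
        sed_prop.index = ["sediment"]
        sed_prop["size_fraction"] = "sediment"
        long = pd.concat([long, sed_prop]).fillna(0.0)
    return long


def occurrence_profiles(table: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-taxon occurrence and read-share summaries across strata.

    Returns one row per taxon with: samples present, total reads, and the
    share of the taxon's reads in each depth and size-fraction level.
    Taxa absent everywhere are dropped with a warning.
    """
    present = table.sum(axis=1) > 0
    if (~present).any():
        warnings.warn(f"dropping {int((~present).sum())} taxa with zero reads")
    table = table.loc[present]
    rows = {}
    for taxon, counts in table.iterrows():
        total = counts.sum()
        row: dict[str, float] = {
            "n_samples": int((counts > 0).sum()),
            "total_reads": int(total),
        }
        for col in ("depth", "size_fraction"):
            shares = counts.groupby(metadata[col]).sum() / total
            for level, share in shares.items():
                row[f"{col}:{level}"] = float(share)
        rows[taxon] = row
    return pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)


def log_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """log10(count + 1) display values for abundance/occurrence plots."""
    return np.log10(table + 1)


def write_rarefaction(curves: Sequence[RarefactionCurve], path) -> None:
    with open(path, "w") as fh:
        fh.write("stratum\tdepth\texpected_richness\n")
        for c in curves:
            for d, s in zip(c.depths, c.expected_richness):
                fh.write(f"{c.stratum}\t{d}\t{s:.4f}\n")
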