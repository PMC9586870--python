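"""Plain-text serialization of cohorts and results.

A cohort round-trips through a directory of TSV/BED/YAML files: windows
(BED4 with CpG counts plus a full TSV with QC/exclusion flags), the count
matrix, sample metadata, class methylomes, array probes, expression values
and the DMR ground truth. Reading the directory back reproduces the
in-memory bundle exactly (pandas writes full float precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import SimConfig
from .containers import CountMatrix
from .simulate import SimulatedCohort, TrueMethylome
from .windows import write_bed


def write_cohort(cohort: SimulatedCohort, outdir) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(cohort.config.to_dict()))
    write_bed(cohort.windows, out / "windows.bed")
    cohort.windows.to_csv(out / "windows.tsv", sep="\t", index=False)
    cohort.cgi.to_csv(out / "cgi.bed", sep="\t", header=False, index=False)
    cohort.counts.counts.to_csv(out / "counts.tsv", sep="\t")
    cohort.samples.to_csv(out / "samples.tsv", sep="\t", float_format="%.17g")
    meth = pd.DataFrame({name: m.beta for name, m in cohort.methylomes.items()})
    meth.index.name = "window"
    meth.to_csv(out / "methylomes.tsv", sep="\t", float_format="%.17g")
    masks = pd.DataFrame({name: m.dmr_mask for name, m in cohort.methylomes.items()})
    masks.index.name = "window"
    masks.to_csv(out / "dmr_masks.tsv", sep="\t")
    cohort.dmr_truth.to_csv(out / "dmr_truth.tsv", sep="\t", index=False)
    cohort.arrays.to_csv(out / "arrays.tsv", sep="\t", index=False, float_format="%.17g")
    cohort.expression.to_csv(out / "expression.tsv", sep="\t", float_format="%.17g")
    return out


def read_cohort(path) -> SimulatedCohort:
    path = Path(path)
    config = SimConfig.from_dict(yaml.safe_load((path / "config.yaml").read_text()))
    windows = pd.read_csv(path / "windows.tsv", sep="\t")
    cgi = pd.read_csv(path / "cgi.bed", sep="\t", header=None,
                      names=["contig", "start", "end"])
    counts_df = pd.read_csv(path / "counts.tsv", sep="\t", index_col=0)
    counts_df.index = pd.RangeIndex(len(counts_df), name="window")
    counts = CountMatrix(counts_df,
                         counts_df.sum(axis=0).astype(float))
    samples = pd.read_csv(path / "samples.tsv", sep="\t", index_col=0,
                          keep_default_na=True, float_precision="round_trip")
    for col in ("role", "batch", "sex", "stage"):
        if col in samples:
            samples[col] = samples[col].fillna("")
    meth = pd.read_csv(path / "methylomes.tsv", sep="\t", index_col=0,
                       float_precision="round_trip")
    masks = pd.read_csv(path / "dmr_masks.tsv", sep="\t", index_col=0)
    methylomes = {
        name: TrueMethylome(meth[name].to_numpy(),
                            "normal" if name == "normal" else name,
                            masks[name].to_numpy().astype(np.int8))
        for name in meth.columns}
    dmr_truth = pd.read_csv(path / "dmr_truth.tsv", sep="\t")
    arrays = pd.read_csv(path / "arrays.tsv", sep="\t",
                         float_precision="round_trip")
    expression = pd.read_csv(path / "expression.tsv", sep="\t", index_col=0,
                             float_precision="round_trip")
    return SimulatedCohort(config=config, windows=windows, cgi=cgi,
                           counts=counts, samples=samples,
                           methylomes=methylomes, dmr_truth=dmr_truth,
                           arrays=arrays, expression=expression)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict())
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    return obj


def write_json(data: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(data), indent=2) + "\n")
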