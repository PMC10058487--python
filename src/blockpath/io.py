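"""Delimited-table I/O, run configuration and report writing.

Blocks are plain CSV/TSV tables: header row of variable ids, first column
sample ids, dot-decimal numbers, missing values as empty cells or ``NA``.
The outcome file has two columns: sample id and class label.

A run configuration (YAML or JSON) names the block files, assigns path
roles, sets the preprocessing options per block and the resampling plan,
and fixes the seed.  ``run_effects`` executes the full pipeline
(preprocess -> effects -> VIP -> fold changes) and writes the tabular and
JSON reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .effects import PathDiagram, PathReport, run_path
from .importance import VIPResult
from .model_selection import CVConfig
from .preprocess import (
    DataBlock,
    Outcome,
    complete_cases,
    encode_outcome,
    log_transform,
    replace_zeros,
    scale_unit_variance,
)

__all__ = [
    "read_block",
    "read_outcome",
    "RunConfig",
    "BlockSpec",
    "load_config",
    "run_effects",
    "write_report",
    "read_report",
    "effects_table",
    "vip_table",
]

logger = logging.getLogger("blockpath")

_NA_STRINGS = {"", "NA", "NaN", "nan", "na"}


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    return pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)


def read_block(path) -> DataBlock:
    """Read a samples x variables table into a DataBlock.

    Locale-independent (dot decimal); empty/NA cells become missing values
    (to be removed later by complete-case filtering); anything else
    non-numeric is an error naming the offending cell.
    """
    path = Path(path)
    df = _read_table(path)
    ids = [str(i) for i in df.index]
    dupes = pd.Index(ids)[pd.Index(ids).duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate sample id {dupes[0]!r} in {path.name}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            cell = str(raw).strip()
            if cell in _NA_STRINGS:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric value {cell!r} at sample {ids[i]!r}, "
                    f"variable {col!r} in {path.name}"
                ) from None
    return DataBlock(
        values=values,
        sample_ids=tuple(ids),
        variable_ids=tuple(str(c) for c in df.columns),
        provenance=(f"read:{path.name}",),
    )


def read_outcome(path, case_label: str | None = None) -> Outcome:
    """Read a two-column (sample id, label) file into an encoded Outcome."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"outcome file {path.name} needs two columns")
    ids = [str(v) for v in df.iloc[:, 0]]
    labels = [str(v).strip() for v in df.iloc[:, 1]]
    return encode_outcome(ids, labels, case_label=case_label)


@dataclass(frozen=True)
class BlockSpec:
    """Per-block file path and preprocessing switches."""

    path: str
    zero_fraction: float = 0.8
    apply_zero_replacement: bool = False
    apply_log: bool = False
    log_base: float = float(np.e)
    scale: bool = True


@dataclass(frozen=True)
class RunConfig:
    """Everything one effects run needs; loadable from YAML or JSON."""

    blocks: dict[str, BlockSpec]
    outcome_path: str
    paths: tuple[PathDiagram, ...]
    out_dir: str
    seed: int
    case_label: str | None = None
    k: int = 10
    repeats: int = 50
    max_components: int | None = None
    n_boot: int = 500
    vip_threshold_global: float = 1.0
    vip_threshold_partial: float = 1.0
    nested_residualization: bool = False
    scale_in_fold: bool = False

    def cv_config(self) -> CVConfig:
        return CVConfig(
            seed=self.seed,
            k=self.k,
            repeats=self.repeats,
            max_components=self.max_components,
            scale_in_fold=self.scale_in_fold,
        )


def load_config(path) -> RunConfig:
    """Parse and validate a YAML/JSON run configuration."""
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    for key in ("blocks", "outcome", "paths", "out_dir", "seed"):
        if key not in raw:
            raise ValueError(f"config is missing required key {key!r}")
    blocks = {}
    for name, spec in raw["blocks"].items():
        if isinstance(spec, str):
            spec = {"path": spec}
        blocks[str(name)] = BlockSpec(
            path=spec["path"],
            zero_fraction=float(spec.get("zero_fraction", 0.8)),
            apply_zero_replacement=bool(spec.get("apply_zero_replacement", False)),
            apply_log=bool(spec.get("apply_log", False)),
            log_base=float(spec.get("log_base", np.e)),
            scale=bool(spec.get("scale", True)),
        )
    diagrams = []
    seen_names = set()
    for p in raw["paths"]:
        d = PathDiagram(
            input_block=p["input"],
            mediator_block=p["mediator"],
            output=p.get("output", "y"),
            name=p.get("name", f"path{len(diagrams) + 1}"),
        )
        if d.input_block not in blocks or d.mediator_block not in blocks:
            raise ValueError(
                f"path {d.name!r} references unknown blocks "
                f"({d.input_block!r}, {d.mediator_block!r})"
            )
        if d.name in seen_names:
            raise ValueError(f"duplicate path name {d.name!r}")
        seen_names.add(d.name)
        diagrams.append(d)
    return RunConfig(
        blocks=blocks,
        outcome_path=raw["outcome"],
        paths=tuple(diagrams),
        out_dir=raw["out_dir"],
        seed=int(raw["seed"]),
        case_label=raw.get("case_label"),
        k=int(raw.get("k", 10)),
        repeats=int(raw.get("repeats", 50)),
        max_components=raw.get("max_components"),
        n_boot=int(raw.get("n_boot", 500)),
        vip_threshold_global=float(raw.get("vip_threshold_global", 1.0)),
        vip_threshold_partial=float(raw.get("vip_threshold_partial", 1.0)),
        nested_residualization=bool(raw.get("nested_residualization", False)),
        scale_in_fold=bool(raw.get("scale_in_fold", False)),
    )


def _preprocess_block(block: DataBlock, spec: BlockSpec) -> tuple[DataBlock, DataBlock]:
    """Apply the configured transformations; returns (scaled, unscaled)
    where 'unscaled' is the transformed-but-unscaled block used for fold
    changes."""
    if spec.apply_zero_replacement:
        block = replace_zeros(block, spec.zero_fraction)
    if spec.apply_log:
        block = log_transform(block, spec.log_base)
    unscaled = block
    if spec.scale:
        block = scale_unit_variance(block)
    return block, unscaled


def run_effects(config: RunConfig) -> list[PathReport]:
    """Execute the full pipeline for every declared path and write reports.

    Writes, under ``config.out_dir``: ``effects.tsv`` (one row per path and
    effect), per-path VIP tables, per-path JSON reports and a plain-text
    log of seeds and selected component counts.  On any error, partial
    outputs are removed and the error re-raised.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        raw_blocks = {
            name: read_block(spec.path) for name, spec in config.blocks.items()
        }
        outcome = read_outcome(config.outcome_path, case_label=config.case_label)
        order = raw_blocks[next(iter(raw_blocks))].sample_ids
        # align every table to a common sample order before filtering
        raw_blocks = {
            name: DataBlock.from_frame(
                b.to_frame().loc[list(order)], provenance=b.provenance
            )
            for name, b in raw_blocks.items()
        }
        idx = [outcome.sample_ids.index(s) for s in order]
        outcome = Outcome(
            sample_ids=order,
            labels=tuple(outcome.labels[i] for i in idx),
            coded=outcome.coded[idx],
            case_label=outcome.case_label,
            control_label=outcome.control_label,
        )
        names = list(raw_blocks)
        filtered, outcome, counts = complete_cases(
            [raw_blocks[n] for n in names], outcome, min_per_class=config.k
        )
        logger.info("complete cases per class: %s", counts)
        scaled, unscaled = {}, {}
        for name, block in zip(names, filtered):
            scaled[name], unscaled[name] = _preprocess_block(
                block, config.blocks[name]
            )
        cv = config.cv_config()
        reports = []
        log_lines = [f"seed\t{config.seed}", f"classes\t{counts}"]
        for diagram in config.paths:
            logger.info("running %s (%s -> %s | %s)", diagram.name,
                        diagram.input_block, diagram.output, diagram.mediator_block)
            report = run_path(
                diagram,
                scaled,
                outcome,
                cv,
                n_boot=config.n_boot,
                vip_threshold_global=config.vip_threshold_global,
                vip_threshold_partial=config.vip_threshold_partial,
                unscaled_blocks=unscaled,
                nested=config.nested_residualization,
            )
            reports.append(report)
            jpath = out_dir / f"{diagram.name}_report.json"
            write_report(report, jpath)
            written.append(jpath)
            for kind, vip_res in (
                ("global", report.vip_global),
                ("partial", report.vip_partial),
            ):
                vpath = out_dir / f"{diagram.name}_vip_{kind}.tsv"
                vip_table(
                    vip_res,
                    report.log2_fc if kind == "global" else None,
                ).to_csv(vpath, sep="\t", index=False)
                written.append(vpath)
            g, p = report.global_estimate, report.partial_estimate
            log_lines += [
                f"{diagram.name}\tglobal components\t{g.n_components_main}",
                f"{diagram.name}\tpartial components\t{p.n_components_main}"
                f"\tC~B\t{p.n_components_CB}\tA~B\t{p.n_components_AB}",
            ]
        epath = out_dir / "effects.tsv"
        effects_table(reports).to_csv(epath, sep="\t", index=False)
        written.append(epath)
        lpath = out_dir / "run.log"
        lpath.write_text("\n".join(log_lines) + "\n")
        written.append(lpath)
        return reports
    except Exception:
        for f in written:
            f.unlink(missing_ok=True)
        raise


def effects_table(reports: list[PathReport]) -> pd.DataFrame:
    """One row per path and effect, mirroring the usual effects summary."""
    rows = []
    for rep in reports:
        d = rep.diagram
        for est, label in (
            (rep.global_estimate, f"{d.input_block} => {d.output} (global)"),
            (
                rep.partial_estimate,
                f"{d.input_block} => {d.output} | {d.mediator_block} (partial)",
            ),
        ):
            rows.append(
                {
                    "path": d.name,
                    "effect": label,
                    "explained_variance_percent": round(est.mean_percent, 2),
                    "sd_percent": round(est.sd_percent, 2),
                    "n_components": est.n_components_main,
                }
            )
    return pd.DataFrame(rows)


def vip_table(
    vip_res: VIPResult, log2_fc: dict[str, float] | None = None
) -> pd.DataFrame:
    """Per-variable VIP report; Log2 FC column left empty (not zero) when
    fold changes are not applicable (residual-block models)."""
    df = pd.DataFrame(
        {
            "variable_id": list(vip_res.variable_ids),
            "observed_vip": np.round(vip_res.observed_vip, 4),
            "boot_mean_vip": np.round(vip_res.boot_mean, 4),
            "boot_sd_vip": np.round(vip_res.boot_sd, 4),
            "important": vip_res.important,
        }
    )
    if log2_fc is not None:
        df["log2_fc"] = [
            "" if log2_fc.get(v) is None else round(log2_fc[v], 4)
            for v in vip_res.variable_ids
        ]
    else:
        df["log2_fc"] = ""
    return df.sort_values("boot_mean_vip", ascending=False, kind="stable").reset_index(
        drop=True
    )


def write_report(report: PathReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)


def read_report(path) -> PathReport:
    with open(path) as fh:
        return PathReport.from_dict(json.load(fh))
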