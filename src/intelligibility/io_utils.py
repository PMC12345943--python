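"""Reading and writing study tables, run configuration, and the pipeline.

The on-disk interchange format is a tidy UTF-8 CSV with one row per
speaker x item x source (three listeners plus one ASR transcript per
stimulus).  The pipeline ties simulate -> score -> analyze -> report into
one deterministic run: identical inputs, configuration and seed produce
byte-identical outputs, and every output embeds a schema version, the
configuration hash and the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import stats as st
from .errors import DataCompletenessError, DegenerateInputError, SchemaError
from .scoring import (
    ASR_SOURCE,
    LISTENER_SOURCES,
    TranscriptionRecord,
    score_study,
)
from .textnorm import EquivalenceLexicon

__all__ = [
    "SCHEMA_VERSION",
    "CSV_COLUMNS",
    "RunConfig",
    "read_transcriptions",
    "write_transcriptions",
    "run_pipeline",
    "render_text_summary",
]

SCHEMA_VERSION = "1.0"

CSV_COLUMNS = [
    "language",
    "group",
    "speaker_id",
    "stimulus_type",
    "item_id",
    "target_text",
    "source",
    "transcript",
]

_VALID_SOURCES = set(LISTENER_SOURCES) | {ASR_SOURCE}


@dataclass
class RunConfig:
    """Everything a reproducible analysis run depends on."""

    input_path: str | None = None
    lexicon_path: str | None = None
    agreement_mode: str = "status"
    run_correlations: bool = True
    run_anova: bool = True
    run_split_plot: bool = True
    run_regressions: bool = True
    run_normality: bool = True
    output_dir: str = "results"
    seed: int = 0
    schema_version: str = SCHEMA_VERSION

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        """Hash of the analysis-relevant settings (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("output_dir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def read_transcriptions(path: str | Path, check_complete: bool = True) -> list[TranscriptionRecord]:
    """Read and validate a tidy transcription CSV.

    Raises :class:`SchemaError` for missing columns or duplicate
    (speaker, item, source) rows and :class:`DataCompletenessError` when a
    stimulus lacks its three listener transcripts or its ASR transcript,
    naming the offending items.
    """
    try:
        df = pd.read_csv(path, encoding="utf-8", dtype=str, keep_default_na=False)
    except UnicodeDecodeError as exc:
        raise SchemaError(f"{path}: not valid UTF-8: {exc}") from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    dup = df.duplicated(subset=["speaker_id", "item_id", "source"], keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()[:10]  # 1-based incl. header
        raise SchemaError(f"{path}: duplicate (speaker, item, source) rows at lines {rows}")
    bad_src = ~df["source"].isin(_VALID_SOURCES)
    if bad_src.any():
        rows = (df.index[bad_src] + 2).tolist()[:10]
        raise SchemaError(f"{path}: unknown source values at lines {rows}")
    records = [
        TranscriptionRecord(**{c: row[c] for c in CSV_COLUMNS})
        for row in df.to_dict("records")
    ]
    if check_complete:
        got = df.groupby(["speaker_id", "item_id"])["source"].apply(set)
        incomplete = sorted(
            f"{spk}/{item}" for (spk, item), s in got.items() if s != _VALID_SOURCES
        )
        if incomplete:
            raise DataCompletenessError(
                f"{path}: stimuli missing listener or ASR rows: {incomplete[:20]}",
                items=incomplete,
            )
    return records


def write_transcriptions(records: list[TranscriptionRecord], path: str | Path) -> None:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=CSV_COLUMNS)
    df.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


# ---------------------------------------------------------------------------
# analysis pipeline


def _round(x, nd=10):
    if isinstance(x, float):
        if math.isnan(x):
            return None
        return round(x, nd)
    return x


def _effects_dict(effects) -> dict:
    return {
        name: {
            "ss": _round(e.ss),
            "df": _round(e.df),
            "F": _round(e.F),
            "p": _round(e.p),
            "partial_eta_sq": _round(e.partial_eta_sq),
        }
        for name, e in effects.items()
    }


def _contrast_dicts(rows) -> list[dict]:
    return [
        {
            "contrast": r.label,
            "estimate": _round(r.estimate),
            "se": _round(r.se),
            "df": _round(r.df),
            "t_ratio": _round(r.t_ratio),
            "p_adj": _round(r.p_adj),
        }
        for r in rows
    ]


def _cell_summary(df: pd.DataFrame, value_cols: list[str], by: list[str]) -> list[dict]:
    out = []
    for keys, sub in df.groupby(by, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        row: dict = dict(zip(by, keys)) | {"n": int(len(sub))}
        for col in value_cols:
            v = sub[col]
            row[col] = {
                "mean": _round(float(v.mean())),
                "sd": _round(float(v.std(ddof=1))) if len(v) > 1 else None,
                "min": _round(float(v.min())),
                "max": _round(float(v.max())),
            }
        out.append(row)
    return out


def run_pipeline(
    config: RunConfig,
    records: list[TranscriptionRecord] | None = None,
) -> dict:
    """Score a study and run the analysis battery; return the report dict.

    ``records`` may be passed directly (e.g. from the simulator); otherwise
    they are read from ``config.input_path``.  The report and the
    per-speaker tables are also written under ``config.output_dir``.
    """
    if records is None:
        if not config.input_path:
            raise SchemaError("run_pipeline needs records or config.input_path")
        records = read_transcriptions(config.input_path)
    lexicon = (
        EquivalenceLexicon.from_file(config.lexicon_path) if config.lexicon_path else None
    )
    word, sentence = score_study(records, lexicon=lexicon, mode=config.agreement_mode)

    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "config_hash": config.digest(),
        "summary": {
            "word_cells": _cell_summary(
                word, ["listener_score", "asr_score", "agreement"], ["language", "group"]
            )
            if len(word)
            else [],
            "sentence_cells": _cell_summary(
                sentence,
                ["listener_score", "asr_score", "asr_success"],
                ["language", "group"],
            )
            if len(sentence)
            else [],
        },
    }

    if config.run_correlations:
        corr: dict = {"word": [], "sentence": []}
        for keys, sub in word.groupby(["language", "group"], sort=True):
            entry = {"language": keys[0], "group": keys[1], "n": int(len(sub))}
            try:
                c = st.pearson(sub["listener_score"], sub["asr_score"])
                entry |= {"r": _round(c.r), "p": _round(c.p)}
            except (DegenerateInputError, ValueError):
                entry |= {"r": None, "p": None, "degenerate": True}
            corr["word"].append(entry)
        for keys, sub in sentence.groupby(["language", "group"], sort=True):
            entry = {"language": keys[0], "group": keys[1], "n": int(len(sub))}
            try:
                c = st.pearson(sub["listener_score"], sub["asr_score"])
                entry |= {"r": _round(c.r), "p": _round(c.p)}
            except (DegenerateInputError, ValueError):
                entry |= {"r": None, "p": None, "degenerate": True}
            corr["sentence"].append(entry)
        report["correlations"] = corr

    if config.run_anova and word["language"].nunique() > 1 and word["group"].nunique() > 1:
        res = st.two_way_anova(
            word["agreement"], word["language"], word["group"], names=("language", "group")
        )
        report["word_anova"] = {
            "effects": _effects_dict(res.effects),
            "ss_error": _round(res.ss_error),
            "df_error": _round(res.df_error),
            "degenerate": res.degenerate,
        }
        if not res.degenerate:
            report["word_contrasts"] = _contrast_dicts(st.emm_pairwise(res))

    if config.run_split_plot and len(sentence):
        merged = word.merge(
            sentence[["speaker_id", "asr_success"]], on="speaker_id", how="inner"
        )
        merged = merged[merged["language"].isin(sentence["language"].unique())]
        if len(merged) and merged["group"].nunique() > 1:
            long = pd.concat(
                [
                    pd.DataFrame(
                        {
                            "y": merged["agreement"],
                            "stimulus": "word",
                            "group": merged["group"],
                            "subject": merged["speaker_id"],
                        }
                    ),
                    pd.DataFrame(
                        {
                            "y": merged["asr_success"],
                            "stimulus": "sentence",
                            "group": merged["group"],
                            "subject": merged["speaker_id"],
                        }
                    ),
                ],
                ignore_index=True,
            )
            try:
                sp = st.split_plot_anova(
                    long["y"], long["group"], long["stimulus"], long["subject"]
                )
                report["split_plot_anova"] = {
                    "effects": _effects_dict(sp.effects),
                    "subject_error": {
                        "ss": _round(sp.ss_subject_error),
                        "df": _round(sp.df_subject_error),
                    },
                    "within_error": {
                        "ss": _round(sp.ss_within_error),
                        "df": _round(sp.df_within_error),
                    },
                    "n_subjects": sp.n_subjects,
                    "n_dropped": sp.n_dropped,
                }
                if sp.ss_within_error > 1e-12:
                    report["stimulus_contrasts"] = _contrast_dicts(st.emm_pairwise(sp))
            except DegenerateInputError:
                report["split_plot_anova"] = {"degenerate": True}

    if config.run_regressions:
        regs: dict = {}
        if len(word):
            labels = word["language"].str.cat(word["group"], sep=" ")
            try:
                rows = st.subgroup_regressions(
                    word["listener_score"], word["agreement"], labels
                )
                regs["word"] = [dataclasses.asdict(r) | {} for r in rows]
                for r in regs["word"]:
                    for k in ("slope", "intercept", "r_sq", "p_slope", "p_adj"):
                        r[k] = _round(r[k])
            except (DegenerateInputError, ValueError):
                regs["word"] = None
        if len(sentence):
            labels = sentence["language"].str.cat(sentence["group"], sep=" ")
            try:
                rows = st.subgroup_regressions(
                    sentence["listener_score"], sentence["asr_success"], labels
                )
                regs["sentence"] = [dataclasses.asdict(r) for r in rows]
                for r in regs["sentence"]:
                    for k in ("slope", "intercept", "r_sq", "p_slope", "p_adj"):
                        r[k] = _round(r[k])
            except (DegenerateInputError, ValueError):
                regs["sentence"] = None
        report["regressions"] = regs

    if config.run_normality:
        norm: dict = {}
        if len(word) >= 4:
            ns = st.normality_screen(word["agreement"])
            norm["word_agreement"] = {
                "skewness": _round(ns.skewness),
                "kurtosis": _round(ns.kurtosis),
                "pass_skew": ns.pass_skew,
                "pass_kurt": ns.pass_kurt,
            }
        if len(sentence) >= 4:
            ns = st.normality_screen(sentence["asr_success"])
            norm["sentence_agreement"] = {
                "skewness": _round(ns.skewness),
                "kurtosis": _round(ns.kurtosis),
                "pass_skew": ns.pass_skew,
                "pass_kurt": ns.pass_kurt,
            }
        report["normality"] = norm

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta_cols = {"schema_version": SCHEMA_VERSION, "seed": config.seed}
    word.assign(**meta_cols).to_csv(
        outdir / "speaker_word_results.csv", index=False, lineterminator="\n"
    )
    sentence.assign(**meta_cols).to_csv(
        outdir / "speaker_sentence_results.csv", index=False, lineterminator="\n"
    )
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )
    contrasts = report.get("word_contrasts", []) + report.get("stimulus_contrasts", [])
    if contrasts:
        pd.DataFrame(contrasts).rename(
            columns={
                "contrast": "Contrast",
                "estimate": "Estimate",
                "se": "SE",
                "df": "df",
                "t_ratio": "t Ratio",
                "p_adj": "p Value",
            }
        ).to_csv(outdir / "contrasts.csv", index=False, lineterminator="\n")
    (outdir / "summary.txt").write_text(render_text_summary(report), encoding="utf-8")
    return report


def _fmt(x, nd=3):
    if x is None:
        return "--"
    return f"{x:.{nd}f}" if isinstance(x, float) else str(x)


def render_text_summary(report: dict) -> str:
    """Plain-text report: per-cell summary stats and contrast tables."""
    lines = [
        "Listener and ASR intelligibility: summary report",
        f"schema {report['schema_version']}  seed {report['seed']}  "
        f"config {report['config_hash']}",
        "",
        "Per-cell summary (mean (SD), range)",
    ]
    for section, cells in report.get("summary", {}).items():
        if not cells:
            continue
        lines.append(f"  [{section}]")
        for cell in cells:
            head = f"    {cell['language']} {cell['group']} (n={cell['n']}):"
            parts = []
            for key, v in cell.items():
                if not isinstance(v, dict):
                    continue
                sd = _fmt(v["sd"], 2)
                parts.append(
                    f"{key} {_fmt(v['mean'], 2)} ({sd}) [{_fmt(v['min'], 2)}-{_fmt(v['max'], 2)}]"
                )
            lines.append(head + " " + "; ".join(parts))
    for name, key in (
        ("Word-level contrasts", "word_contrasts"),
        ("Stimulus contrasts", "stimulus_contrasts"),
    ):
        rows = report.get(key)
        if not rows:
            continue
        lines += ["", name, "  Contrast | Estimate | SE | df | t Ratio | p Value"]
        for r in rows:
            lines.append(
                f"  {r['contrast']} | {_fmt(r['estimate'], 3)} | {_fmt(r['se'], 3)} | "
                f"{_fmt(r['df'], 1)} | {_fmt(r['t_ratio'], 2)} | {_fmt(r['p_adj'], 4)}"
            )
    return "\n".join(lines) + "\n"
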