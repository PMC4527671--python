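"""End-to-end orchestration of the lifespan and qPCR analyses.

A :class:`RunConfig` (loadable from a YAML file) names the inputs, the
control-group mapping, and the analysis options; the two pipeline entry
points chain the stages and return a :class:`RunReport` whose contents are
also written as TSV + full-precision JSON under the configured output
directory.  Runs are deterministic given the same inputs, config, and seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import io as rio
from .gompertz import summarize_lifespan
from .qpcr import (
    CtTable,
    call_de,
    collapse_technical,
    consensus_ranking,
    fold_change_contrast,
)
from .survival import gehan_breslow_wilcoxon, logrank, modified_ks, wang_allison

log = logging.getLogger("radspan")

EXIT_OK = 0
EXIT_SCHEMA = 2
EXIT_CONVERGENCE = 3


@dataclass
class RunConfig:
    """Run configuration; every field is echoed into the RunReport."""

    lifespan_csv: str | None = None
    ct_csv: str | None = None
    efficiency_csv: str | None = None
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "info"
    # lifespan options
    control_map: dict[str, str] = field(default_factory=dict)
    merge_controls: bool = False          # pool all control groups per sex into one
    survival_tests: tuple[str, ...] = ("modified_ks", "logrank", "gehan", "wang_allison")
    gompertz_bin_width: float = 5.0
    # qPCR options
    reference_candidates: list[str] = field(default_factory=list)
    forced_references: list[str] = field(default_factory=list)
    n_ref: int = 2
    target_genes: list[str] = field(default_factory=list)
    contrast_groups: list[list[str]] = field(default_factory=list)  # [exposed, control]
    p_test: str = "welch"
    min_abs_log2fc: float = 1.0
    de_alpha: float = 0.05
    rel_sd_threshold: float = 0.05
    min_efficiency: float = 1.9
    benjamini_hochberg: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise rio.SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunReport:
    tool_version: str
    config: dict
    outputs: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


_TEST_FUNCS = {
    "modified_ks": modified_ks,
    "logrank": logrank,
    "gehan": gehan_breslow_wilcoxon,
    "wang_allison": wang_allison,
}


def _merged_controls(df: pd.DataFrame, control_map: Mapping[str, str]) -> tuple[pd.DataFrame, dict]:
    """Pool all control groups of each sex into one merged control label."""
    controls = sorted(set(control_map.values()))
    df = df.copy()
    new_map = dict(control_map)
    for sex in df["sex"].unique():
        sex_controls = [c for c in controls if (df["group"].eq(c) & df["sex"].eq(sex)).any()]
        if len(sex_controls) > 1:
            merged = f"control_{sex}_merged"
            df.loc[df["group"].isin(sex_controls) & df["sex"].eq(sex), "group"] = merged
            for k, v in control_map.items():
                if v in sex_controls:
                    new_map[k] = merged
    return df, new_map


def run_lifespan_pipeline(config: RunConfig) -> RunReport:
    """Kaplan-Meier summaries, Gompertz fits, and the four survival tests."""
    from . import __version__

    if not config.lifespan_csv:
        raise rio.SchemaError("config.lifespan_csv is required")
    df = rio.read_lifespan_csv(config.lifespan_csv)
    control_map = dict(config.control_map)
    if not control_map:
        raise rio.SchemaError("config.control_map is required for the lifespan pipeline")
    if config.merge_controls:
        df, control_map = _merged_controls(df, control_map)

    summaries = summarize_lifespan(df, control_map, bin_width=config.gompertz_bin_width)
    warnings_list = [f"quantile unreached for group {s.group}"
                     for s in summaries if s.median is None or s.age90 is None]
    warnings_list += [f"too few hazard bins to score fit for group {s.group}"
                      for s in summaries if s.r_squared is None]

    tests = []
    for group, ctrl in sorted(control_map.items()):
        if group == ctrl:
            continue
        a = df.loc[df["group"] == group, "age_days"].to_numpy()
        b = df.loc[df["group"] == ctrl, "age_days"].to_numpy()
        for name in config.survival_tests:
            res = _TEST_FUNCS[name](a, b, groups=(group, ctrl))
            tests.append(res)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rio.write_summary_tsv(summaries, out_dir / "lifespan_summary.tsv")
    report = RunReport(
        tool_version=__version__,
        config=dataclasses.asdict(config),
        outputs={"summaries": summaries, "tests": tests},
        warnings=warnings_list,
    )
    rio.write_json_report(report, out_dir / "lifespan_report.json")
    test_rows = pd.DataFrame([{
        "test": t.name, "group": t.groups[0], "control": t.groups[1],
        "statistic": round(t.statistic, 4), "p_value": f"{t.p_value:.4g}",
    } for t in tests])
    test_rows.to_csv(out_dir / "lifespan_tests.tsv", sep="\t", index=False)
    return report


def run_qpcr_pipeline(config: RunConfig) -> RunReport:
    """Stability rating -> reference selection -> contrasts -> DE flags."""
    from . import __version__

    if not (config.ct_csv and config.efficiency_csv):
        raise rio.SchemaError("config.ct_csv and config.efficiency_csv are required")
    raw = rio.read_ct_csv(config.ct_csv)
    eff = rio.read_efficiencies_csv(config.efficiency_csv)
    wide, qc = collapse_technical(raw)
    meta = (raw[["sample_id", "group", "bio_rep"]].drop_duplicates()
            .set_index("sample_id").sort_index())
    warnings_list = [f"flagged reaction ({r.gene}, {r.sample_id}): sd={r.sd_ct}"
                     for r in qc[qc["flagged"]].itertuples()]

    candidates = config.reference_candidates or sorted(wide.index)
    report_stab = consensus_ranking(wide, candidates, eff,
                                    groups=meta["group"], n_ref=config.n_ref)
    references = list(config.forced_references) or report_stab.selected
    for ref in references:
        if ref not in wide.index:
            raise rio.SchemaError(f"designated reference gene {ref!r} missing from Ct table")

    table = CtTable(ct=wide, sample_meta=meta, efficiencies=eff,
                    reference_genes=references, flags=qc[qc["flagged"]],
                    min_efficiency=config.min_efficiency)

    contrasts = []
    for gene in config.target_genes:
        for exposed, control in config.contrast_groups:
            contrasts.append(fold_change_contrast(
                table, gene, exposed, control, p_test=config.p_test))
    contrasts = call_de(contrasts, min_abs_log2fc=config.min_abs_log2fc,
                        alpha=config.de_alpha, rel_sd_threshold=config.rel_sd_threshold)
    if config.benjamini_hochberg and contrasts:
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([c.p_value for c in contrasts], method="fdr_bh")[1]
        for c, q in zip(contrasts, adj):
            c.extra["q_value"] = float(q)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stab_tsv = pd.concat([report_stab.scores.round(4), report_stab.ranks.add_suffix("_rank"),
                          report_stab.consensus.round(3)], axis=1)
    stab_tsv.to_csv(out_dir / "qpcr_stability.tsv", sep="\t")
    contrast_rows = pd.DataFrame([{
        "gene": c.gene, "exposed": c.exposed_group, "control": c.control_group,
        "mean_log2_fc": round(c.mean_log2_fc, 4), "sd_log2_fc": round(c.sd_log2_fc, 4),
        "p_value": f"{c.p_value:.4g}", "de": c.de,
    } for c in contrasts])
    contrast_rows.to_csv(out_dir / "qpcr_contrasts.tsv", sep="\t", index=False)
    report = RunReport(
        tool_version=__version__,
        config=dataclasses.asdict(config),
        outputs={"stability": report_stab, "references": references, "contrasts": contrasts},
        warnings=warnings_list,
    )
    rio.write_json_report(report, out_dir / "qpcr_report.json")
    return report
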