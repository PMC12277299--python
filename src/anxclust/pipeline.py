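"""End-to-end analysis: per-stratum clustering reports, paired comparison,
and the height-fraction sensitivity check.

Everything written to disk is deterministic for a fixed configuration (no
timestamps), so re-running a config yields byte-identical reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .datasets import FIXTURES, Dataset, bundled_fixture, load_dataset
from .hierarchy import LINKAGES, cut_at_fraction
from .model import HierarchicalAnxietyModel, PairedActivityModel
from .simulate import recovery_score

__all__ = ["AnalysisConfig", "run_analysis", "sensitivity"]


@dataclass
class AnalysisConfig:
    """Inputs and tuning knobs of one pipeline run.

    `low_input` / `high_input` / `paired_input` may be fixture names
    (e.g. "table1_low") or CSV paths; any of them may be None to skip that
    stage.
    """

    low_input: str | None = "table1_low"
    high_input: str | None = "table2_high"
    paired_input: str | None = "table3_paired"
    linkage: str = "ward"
    fraction: float = 0.20
    k_range: tuple[int, int] = (2, 10)
    sensitivity_fractions: tuple[float, ...] = (0.15, 0.25)
    seed: int = 2018
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.linkage not in LINKAGES:
            raise ValueError(f"linkage must be one of {LINKAGES}")
        for f in (self.fraction, *self.sensitivity_fractions):
            if not 0.0 < f <= 1.0:
                raise ValueError(f"fractions must be in (0, 1], got {f}")
        lo, hi = self.k_range
        if not 2 <= lo <= hi:
            raise ValueError(f"invalid k_range {self.k_range}")


def _load(source: str, group: str) -> Dataset:
    if source in FIXTURES:
        return bundled_fixture(source)
    return load_dataset(source, group)


def _write(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(text)


def run_analysis(config: AnalysisConfig) -> dict:
    """Run the full pipeline; returns the report bundle, writing files when
    `config.out_dir` is set.

    Per stratum: dendrogram (Newick + JSON), membership table, cluster table
    with rounded mean percentages, and the validation-metric JSON. Plus the
    paired comparison table and a plain-text run log.
    """
    out = Path(config.out_dir) if config.out_dir else None
    # out_dir is excluded from serialized reports so identical configs give
    # byte-identical output wherever they are written
    cfg = {k: v for k, v in asdict(config).items() if k != "out_dir"}
    bundle: dict = {"config": cfg, "version": __version__}
    log = [
        f"anxclust {__version__}",
        f"seed={config.seed} linkage={config.linkage} fraction={config.fraction}",
    ]

    for group, source in (("low", config.low_input), ("high", config.high_input)):
        if source is None:
            continue
        stage = f"cluster[{group}]"
        try:
            data = _load(source, group)
            n = data.n
            k_range = (config.k_range[0], min(config.k_range[1], n - 1))
            res = HierarchicalAnxietyModel(data, linkage=config.linkage).fit(
                fraction=config.fraction, k_range=k_range
            )
        except Exception as exc:
            raise RuntimeError(f"{stage}: {exc}") from exc
        bundle[group] = res
        log.append(
            f"{stage}: n={n} k={res.k} dendrogram_k={res.selection.dendrogram_k} "
            f"silhouette_best_k={res.selection.chosen_k} "
            f"silhouette={res.quality.silhouette_mean:.3f}"
        )
        if out:
            gdir = out / group
            _write(gdir / "dendrogram.nwk", res.newick())
            _write(gdir / "dendrogram.json", res.dendrogram_json())
            _write(gdir / "quality.json", res.to_json())
            _write(gdir / "summary.txt", res.summary())
            gdir.mkdir(parents=True, exist_ok=True)
            res.membership_frame().to_csv(gdir / "membership.csv", index=False)
            res.cluster_table().to_csv(gdir / "clusters.csv", index=False)

    if config.paired_input is not None:
        stage = "paired-comparison"
        try:
            source = config.paired_input
            paired = bundled_fixture(source) if source in FIXTURES else pd.read_csv(source)
            cres = PairedActivityModel(paired).fit()
        except Exception as exc:
            raise RuntimeError(f"{stage}: {exc}") from exc
        bundle["paired"] = cres
        log.append(f"{stage}: rows={len(cres.comparisons)}")
        if out:
            _write(out / "comparison_summary.txt", cres.summary())
            out.mkdir(parents=True, exist_ok=True)
            cres.frame.to_csv(out / "comparison.csv", index=False)

    if out:
        _write(out / "run_log.txt", "\n".join(log) + "\n")
        machine = {
            "config": cfg,
            "version": __version__,
            "groups": {
                g: bundle[g].to_dict() for g in ("low", "high") if g in bundle
            },
        }
        _write(out / "summary.json", json.dumps(machine, indent=2, sort_keys=True))
    bundle["log"] = log
    return bundle


def sensitivity(config: AnalysisConfig) -> pd.DataFrame:
    """Compare partitions across dendrogram cut fractions.

    For each stratum and each fraction (the default plus the alternates),
    reports the resulting k and the adjusted Rand index against the
    default-fraction partition.
    """
    fractions = (config.fraction, *config.sensitivity_fractions)
    if len(fractions) < 2:
        raise ValueError("need at least 2 fractions for a sensitivity analysis")
    rows = []
    for group, source in (("low", config.low_input), ("high", config.high_input)):
        if source is None:
            continue
        data = _load(source, group)
        model = HierarchicalAnxietyModel(data, linkage=config.linkage)
        reference = cut_at_fraction(model.dendrogram, config.fraction)
        for frac in fractions:
            part = cut_at_fraction(model.dendrogram, frac)
            rows.append(
                {
                    "group": group,
                    "fraction": frac,
                    "k": part.k,
                    "ari_vs_default": recovery_score(reference, part),
                }
            )
    df = pd.DataFrame(rows)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "sensitivity.csv", index=False)
    return df
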