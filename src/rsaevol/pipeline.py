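"""End-to-end pipeline orchestration.

Wires the modules into the three-stage analysis -- data preparation
(encoding and REV estimation), jackknifing (replicate branch-length fits
under the heterotachy or partition model), and data summarising (ln(L)
statistics, filters, classification, clade summaries) -- driven by a
:class:`RunConfig` whose defaults are the analysis settings this package
standardises on: 100 delete-half replicates, a 3-class heterotachy mixture,
8 site-diversity categories, a 5e-5 branch-length floor, an IQR < 6
robustness filter (probed also at 4 and 5), Cliff's delta >= 0.7 with
Holm-adjusted p < 1e-4 (partition consensus at 0.6), and reporting delta
thresholds 0.3..0.7.
"""

from __future__ import annotations

import dataclasses
import json
import platform
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, compare, encoding, engine, io, revmodel


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    """All knobs of one pipeline run; defaults are the standard analysis.

    Channel ``rsa20``/``rsa10`` derives the second alignment from an RSA
    profile; ``aa`` compares an explicitly supplied second FASTA; ``custom``
    uses a user alphabet map on the 20-category encoding.
    """

    alignment: str = ""
    tree: str = ""
    rsa_profile: str | None = None
    second_alignment: str | None = None
    channel: str = "rsa20"                 # aa | rsa20 | rsa10 | custom
    custom_map: str | None = None
    mode: str = "heterotachy"              # heterotachy | partition | consensus
    n_classes: int = 3
    n_categories: int = 8
    min_category_fraction: float = 0.05
    n_replicates: int = 100
    jackknife_fraction: float = 0.5
    seed: int = 0
    min_len: float = compare.LENGTH_FLOOR
    floor: float = compare.LENGTH_FLOOR
    iqr_max: float = compare.IQR_MAX
    iqr_probes: tuple[float, ...] = compare.IQR_PROBES
    delta_min: float = compare.DELTA_MIN_HETEROTACHY
    partition_delta_min: float = compare.DELTA_MIN_PARTITION
    p_max: float = compare.P_MAX
    delta_thresholds: tuple[float, ...] = compare.DELTA_THRESHOLDS
    zero_set_max_ratio: int = compare.ZERO_SET_MAX_RATIO
    aa_model: str | None = None            # PAML path; estimated if absent
    second_model: str | None = None
    clades: str | None = None              # YAML clade -> branch labels
    family: str = "family"
    outdir: str = "rsaevol_out"

    def validate(self) -> None:
        if self.channel not in ("aa", "rsa20", "rsa10", "custom"):
            raise ConfigError(f"unknown channel {self.channel!r}")
        if self.mode not in ("heterotachy", "partition", "consensus"):
            raise ConfigError(f"unknown engine mode {self.mode!r}")
        if self.channel in ("rsa20", "rsa10", "custom") and not self.rsa_profile:
            raise ConfigError(
                f"channel {self.channel!r} requires an RSA profile"
            )
        if self.channel == "aa" and not self.second_alignment:
            raise ConfigError("channel 'aa' requires a second alignment")
        if self.channel == "custom" and not self.custom_map:
            raise ConfigError("channel 'custom' requires an alphabet map")
        if not 0 < self.jackknife_fraction <= 1:
            raise ConfigError("jackknife fraction must be in (0, 1]")
        if not (0 <= self.p_max <= 1):
            raise ConfigError("p_max must be a probability")
        if self.n_classes < 1 or self.n_categories < 2:
            raise ConfigError("n_classes >= 1 and n_categories >= 2 required")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        cfg = cls(**data)
        for name in ("iqr_probes", "delta_thresholds"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["iqr_probes"] = list(self.iqr_probes)
        d["delta_thresholds"] = list(self.delta_thresholds)
        return d


@dataclass
class RunResult:
    outputs: dict[str, str]
    calls: dict[str, str]
    comparisons: list
    manifest: dict = field(default_factory=dict)


def _derive_seed(seed: int, tag: str) -> int:
    tag_int = zlib.crc32(tag.encode())    # process-independent, unlike hash()
    return int(np.random.default_rng([seed, tag_int]).integers(2**31))


def _load_channels(cfg: RunConfig):
    aa = io.read_fasta(cfg.alignment)
    if cfg.channel == "aa":
        second = io.read_fasta(cfg.second_alignment)
        return aa, second, None
    profile = io.read_rsa_profile(cfg.rsa_profile, aa)
    if cfg.channel == "rsa20":
        second = encoding.encode_rsa20(profile)
    elif cfg.channel == "rsa10":
        second = encoding.encode_rsa10(profile)
    else:
        amap = encoding.AlphabetMap.from_file(cfg.custom_map)
        second = encoding.reduce_alphabet(
            encoding.encode_rsa20(profile), amap
        )
    return aa, second, profile


def _channel_model(cfg_path, alignment, tree):
    if cfg_path:
        return revmodel.read_paml(cfg_path, alignment.alphabet)
    return revmodel.estimate_rev(alignment, tree)


def run_pipeline(config: RunConfig) -> RunResult:
    """Run the full analysis and write the output bundle.

    Outputs: the derived channel alignment (FASTA), both REV matrices
    (PAML text), the branch table (TSV), branch comparisons (TSV), the
    NHX-annotated tree, a clade summary (JSON) when clades are supplied,
    and a run manifest (JSON) recording versions, seeds, thresholds and
    stage timings.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    timings: dict[str, float] = {}
    stage = "data-preparation"
    try:
        t0 = time.perf_counter()
        aa_aln, second_aln, _profile = _load_channels(config)
        tree = io.read_newick(config.tree, leaf_names=aa_aln.taxon_names)
        paa_path = outdir / "channel2.fasta"
        second_aln.write_fasta(paa_path)
        outputs["channel2_fasta"] = str(paa_path)
        aa_model = _channel_model(config.aa_model, aa_aln, tree)
        second_model = _channel_model(config.second_model, second_aln, tree)
        for name, model in (("aa", aa_model), ("channel2", second_model)):
            p = outdir / f"rev_{name}.paml"
            revmodel.write_paml(model, p)
            outputs[f"rev_{name}"] = str(p)
        timings[stage] = time.perf_counter() - t0

        stage = "jackknifing"
        t0 = time.perf_counter()
        reps = compare.jackknife_replicates(
            aa_aln, n=config.n_replicates,
            fraction=config.jackknife_fraction,
            seed=_derive_seed(config.seed, "jackknife"),
        )
        mode = "heterotachy" if config.mode == "consensus" else config.mode
        table = compare.build_branch_table(
            aa_aln, second_aln, tree, aa_model, second_model, reps,
            mode=mode, H=config.n_classes, n_categories=config.n_categories,
        )
        part_table = None
        if config.mode == "consensus":
            part_table = compare.build_branch_table(
                aa_aln, second_aln, tree, aa_model, second_model, reps,
                mode="partition", n_categories=config.n_categories,
            )
        table_path = outdir / "branch_table.tsv"
        table.to_tsv(table_path)
        outputs["branch_table"] = str(table_path)
        timings[stage] = time.perf_counter() - t0

        stage = "data-summarizing"
        t0 = time.perf_counter()
        comparisons = compare.compare_branches(
            table, min_len=config.min_len, floor=config.floor,
            iqr_max=config.iqr_max,
            seed=_derive_seed(config.seed, "zero-set"),
            max_ratio=config.zero_set_max_ratio,
        )
        part_comparisons = None
        if part_table is not None:
            part_comparisons = compare.compare_branches(
                part_table, min_len=config.min_len, floor=config.floor,
                iqr_max=config.iqr_max,
                seed=_derive_seed(config.seed, "zero-set-partition"),
                max_ratio=config.zero_set_max_ratio,
            )
        calls = compare.classify_branches(
            comparisons, delta_min=config.delta_min, p_max=config.p_max,
            partition_comparisons=part_comparisons,
            partition_delta_min=config.partition_delta_min,
        )
        frame = compare.comparisons_to_frame(comparisons, calls)
        cmp_path = outdir / "branch_comparisons.tsv"
        frame.to_csv(cmp_path, sep="\t", index=False)
        outputs["branch_comparisons"] = str(cmp_path)
        tree_path = outdir / "annotated_tree.nhx"
        io.write_annotated_tree(tree, calls, tree_path)
        outputs["annotated_tree"] = str(tree_path)

        summary = {
            "tree_summary": {
                str(k): v
                for k, v in compare.tree_summary(
                    comparisons, config.delta_thresholds
                ).items()
            },
            "iqr_probe_kept_fraction": {
                str(thr): _kept_fraction(comparisons, thr)
                for thr in config.iqr_probes
            },
        }
        if config.clades:
            with open(config.clades) as fh:
                clade_map = yaml.safe_load(fh)
            all_lnL = np.concatenate(
                [c.lnL for c in comparisons if c.lnL.size]
            )
            med, shift = compare.family_sensitivity(all_lnL)
            clades = compare.summarize_clades(
                {config.family: calls}, clade_map,
                thresholds={
                    "delta_min": config.delta_min, "p_max": config.p_max,
                },
                mode=config.mode,
                family_stats={config.family: {
                    "median_lnL": med, "mean_shift": shift,
                }},
            )
            summary["clades"] = [c.to_json_dict() for c in clades]
        summary_path = outdir / "summary.json"
        with open(summary_path, "w") as fh:
            json.dump(summary, fh, indent=1)
        outputs["summary"] = str(summary_path)
        timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    manifest = {
        "package": "rsaevol",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": config.to_dict(),
        "seeds": {
            "root": config.seed,
            "jackknife": _derive_seed(config.seed, "jackknife"),
            "zero_set": _derive_seed(config.seed, "zero-set"),
        },
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "outputs": outputs,
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    outputs["manifest"] = str(manifest_path)
    return RunResult(outputs, calls, comparisons, manifest)


def _kept_fraction(comparisons, threshold: float) -> float:
    iqrs = np.array([
        c.iqr for c in comparisons
        if np.isfinite(c.iqr) and c.reason != "near_zero"
    ])
    if iqrs.size == 0:
        return float("nan")
    return float((iqrs < threshold).mean())


class PipelineError(RuntimeError):
    """A stage failed; partial outputs remain on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
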