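"""Population summaries, the ROH-count purity screen, and the end-to-end
pipeline driver.

The purity screen applies the headline decision rule: populations whose mean
per-individual ROH count exceeds 20 look like closed purebred lines;
populations below 6 look like F1 crossbreds; the band in between is
*indeterminate* — the rule is a screen, not a classifier, and real
populations do fall in the gap.
"""

from __future__ import annotations

import datetime
import platform
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genotypes import DEFAULT_AUTOSOMES, GenotypeMatrix
from .ld import PopulationLD, population_mean_ld
from .plink import read_genotypes
from .popstruct import (
    classical_mds,
    hudson_fst_matrix,
    ibs_distance_matrix,
    neighbor_joining_tree,
)
from .qc import QCThresholds, apply_qc
from .roh import (
    ROHParams,
    call_roh,
    froh_all_samples,
    froh_to_frame,
    roh_population_summary,
    segments_to_frame,
)
from .simulate import (
    BreedSpec,
    CrossSpec,
    SimScenario,
    simulate_panel,
)

PUREBRED_MIN_ROH = 20.0  # mean ROH count above which a population looks purebred
CROSSBRED_MAX_ROH = 6.0  # mean ROH count below which it looks F1-crossbred


@dataclass(frozen=True)
class PurityCall:
    """Screen verdict for one population."""

    population: str
    mean_roh_count: float
    call: str  # purebred-like | crossbred-like | indeterminate
    purebred_min: float
    crossbred_max: float


def summarize(
    g: GenotypeMatrix,
    segments,
    froh_results,
    ld_results: dict[str, PopulationLD] | None = None,
    labels: dict[str, str] | None = None,
    length_metric: str = "mean",
) -> pd.DataFrame:
    """Per-population summary table: ROH count, ROH length, F_ROH and mean LD.

    Rows are ordered by population name.  ``ld_results`` maps population ->
    :class:`~rohscan.ld.PopulationLD`; populations without an entry get NaN
    LD columns.
    """
    labels = labels or g.population_map()
    orphans = [r.sample_id for r in froh_results if r.sample_id not in labels]
    if orphans:
        raise KeyError(f"froh results for unlabelled samples: {orphans}")
    table = roh_population_summary(froh_results, segments, labels, length_metric)
    if ld_results:
        table["ld_mean"] = [
            ld_results[p].mean_r2 if p in ld_results else np.nan
            for p in table["population"]
        ]
        table["ld_se"] = [
            ld_results[p].se_r2 if p in ld_results else np.nan
            for p in table["population"]
        ]
    else:
        table["ld_mean"] = np.nan
        table["ld_se"] = np.nan
    return table.sort_values("population", ignore_index=True)


def purity_call(
    summary_row,
    purebred_min: float = PUREBRED_MIN_ROH,
    crossbred_max: float = CROSSBRED_MAX_ROH,
) -> PurityCall:
    """Classify one summary row by its mean per-individual ROH count."""
    mean_count = float(summary_row["roh_count_mean"])
    if mean_count > purebred_min:
        call = "purebred-like"
    elif mean_count < crossbred_max:
        call = "crossbred-like"
    else:
        call = "indeterminate"
    return PurityCall(
        population=str(summary_row["population"]),
        mean_roh_count=mean_count,
        call=call,
        purebred_min=purebred_min,
        crossbred_max=crossbred_max,
    )


def purity_table(summary: pd.DataFrame, **kwargs) -> pd.DataFrame:
    calls = [purity_call(row, **kwargs) for _, row in summary.iterrows()]
    return pd.DataFrame([asdict(c) for c in calls])


def _scenario_from_config(cfg: dict) -> SimScenario:
    breeds = [BreedSpec(**b) for b in cfg.get("breeds", [])]
    crosses = [CrossSpec(**c) for c in cfg.get("crosses", [])]
    keys = {
        k: cfg[k]
        for k in (
            "n_chrom",
            "chrom_length_bp",
            "snp_spacing_bp",
            "recomb_rate_cm_per_mb",
            "sample_sizes",
            "seed",
        )
        if k in cfg
    }
    if "freq_range" in cfg:
        keys["freq_range"] = tuple(cfg["freq_range"])
    return SimScenario(breeds=breeds, crosses=crosses, **keys)


def load_config(source) -> dict:
    """Accept a config dict directly or a YAML file path."""
    if isinstance(source, dict):
        return source
    import yaml

    with open(source) as fh:
        return yaml.safe_load(fh)


def run_pipeline(config, out_dir) -> dict:
    """Run QC -> ROH -> LD -> structure -> report and write all artifacts.

    ``config`` is a dict (or YAML path) with sections:

    * ``input``: ``{path_prefix, format}`` to load a PLINK file set, **or**
      ``simulate``: a scenario block (``breeds``, ``crosses``, geometry,
      ``seed``) to generate one;
    * ``autosomes`` (optional): chromosome labels to keep (default 1–28);
    * ``qc``: ``{maf, hwe_p, call_rate, hwe_scope, enabled}``;
    * ``roh``: any :class:`~rohscan.roh.ROHParams` field;
    * ``ld``: ``{scheme, window_kb}``.

    Returns a dict of the in-memory results; writes TSV/Newick artifacts and
    ``run_log.txt`` into ``out_dir``.  Deterministic for a fixed config.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"rohscan {__version__} on python {platform.python_version()}",
        f"started {datetime.datetime.now().isoformat(timespec='seconds')}",
        f"config: {cfg!r}",
    ]

    def stage(name):
        log_lines.append(f"stage: {name}")

    try:
        if "simulate" in cfg:
            stage("simulate")
            scenario = _scenario_from_config(cfg["simulate"])
            g, truth = simulate_panel(scenario, out_prefix=out / "panel")
            log_lines.append(
                f"simulated {g.n_samples} samples x {g.n_snps} SNPs, "
                f"seed {scenario.seed}"
            )
        elif "input" in cfg:
            stage("load")
            g = read_genotypes(
                cfg["input"]["path_prefix"], cfg["input"].get("format", "auto")
            )
            truth = None
        else:
            raise ValueError("config needs an 'input' or 'simulate' section")

        autosomes = set(map(str, cfg.get("autosomes", sorted(DEFAULT_AUTOSOMES))))
        present = [c for c in g.chroms if c in autosomes]
        if set(g.chroms) - set(present):
            stage("autosome-restriction")
            g = g.restrict_chroms(present)
            log_lines.append(f"kept {g.n_snps} autosomal SNPs")

        qc_cfg = cfg.get("qc", {})
        if qc_cfg.get("enabled", True):
            stage("qc")
            thresholds = QCThresholds(
                maf_max_removed=qc_cfg.get("maf", 0.05),
                hwe_p_max_removed=qc_cfg.get("hwe_p", 1e-4),
                callrate_max_removed=qc_cfg.get("call_rate", 0.95),
            )
            g, qc_report = apply_qc(
                g, thresholds, hwe_scope=qc_cfg.get("hwe_scope", "pooled")
            )
            qc_report.to_tsv(out / "qc_report.tsv")
            log_lines.append(
                f"QC: {qc_report.n_retained}/{qc_report.n_input} SNPs retained "
                f"(thresholds {thresholds})"
            )
        else:
            qc_report = None
            log_lines.append("QC disabled")

        stage("roh")
        roh_params = ROHParams(**cfg.get("roh", {}))
        segments = call_roh(g, roh_params)
        froh = froh_all_samples(segments, g)
        segments_to_frame(segments).to_csv(
            out / "roh_segments.tsv", sep="\t", index=False, float_format="%.10g"
        )
        froh_to_frame(froh).to_csv(
            out / "froh.tsv", sep="\t", index=False, float_format="%.10g"
        )
        log_lines.append(f"ROH: {len(segments)} segments ({roh_params})")

        stage("ld")
        ld_cfg = cfg.get("ld", {})
        ld_results: dict[str, PopulationLD] = {}
        pair_frames = []
        for pop in sorted(set(g.populations)):
            sub = g.subset(
                sample_keep=[s.sample_id for s in g.samples if s.population == pop]
            )
            try:
                res = population_mean_ld(
                    sub,
                    scheme=ld_cfg.get("scheme", "adjacent"),
                    window_kb=ld_cfg.get("window_kb"),
                )
            except ValueError as exc:
                log_lines.append(f"LD skipped for {pop}: {exc}")
                continue
            ld_results[pop] = res
            frame = res.pairs.copy()
            frame.insert(0, "population", pop)
            pair_frames.append(frame)
        if pair_frames:
            pd.concat(pair_frames, ignore_index=True).to_csv(
                out / "ld_pairs.tsv", sep="\t", index=False, float_format="%.10g"
            )

        stage("structure")
        structure: dict = {}
        if g.n_samples >= 2:
            ibs = ibs_distance_matrix(g)
            ibs.to_tsv(out / "ibs_distances.tsv")
            mds = classical_mds(ibs, k=2)
            mds.to_frame(g.population_map()).to_csv(
                out / "mds_coordinates.tsv", sep="\t", index=False,
                float_format="%.10g",
            )
            structure["ibs"] = ibs
            structure["mds"] = mds
        pop_sizes = pd.Series(g.populations).value_counts()
        if (pop_sizes >= 2).sum() >= 2:
            fst = hudson_fst_matrix(g)
            fst.to_tsv(out / "fst_matrix.tsv")
            structure["fst"] = fst
            if len(fst.populations) >= 3:
                tree = neighbor_joining_tree(fst)
                (out / "nj_tree.nwk").write_text(tree.newick + "\n")
                structure["tree"] = tree

        stage("report")
        summary = summarize(g, segments, froh, ld_results)
        summary.to_csv(out / "population_summary.tsv", sep="\t", index=False,
                       float_format="%.10g")
        purity = purity_table(summary)
        purity.to_csv(out / "purity_calls.tsv", sep="\t", index=False,
                      float_format="%.10g")
    except Exception as exc:
        stages = [ln for ln in log_lines if ln.startswith("stage: ")]
        failed_stage = stages[-1].removeprefix("stage: ") if stages else "setup"
        log_lines.append(f"FAILED at stage {failed_stage}: {exc!r}")
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
        raise RuntimeError(f"pipeline failed at stage {failed_stage}: {exc}") from exc

    log_lines.append("finished")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return {
        "genotypes": g,
        "truth": truth,
        "qc_report": qc_report,
        "segments": segments,
        "froh": froh,
        "ld": ld_results,
        "summary": summary,
        "purity": purity,
        **structure,
    }
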