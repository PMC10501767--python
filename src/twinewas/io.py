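"""Delimited-text readers/writers, run configuration, and the pipeline runner.

All tables are tab-separated text (gzip accepted transparently), "." for
missing values, 1-based genomic positions.  Output files carry a header
comment with the tool version, the seed, and SHA-256 checksums of the inputs
they were derived from; readers skip '#' comment lines.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .preprocess import (
    DEFAULT_COVARIATES,
    GROUPS,
    MethylationMatrix,
    PairTable,
    classify_pairs,
    filter_probes,
    residualize,
)

logger = logging.getLogger("twinewas")

__all__ = [
    "read_table",
    "write_table",
    "read_methylation",
    "read_annotation",
    "read_gwas_hits",
    "read_sample_sheet",
    "write_cohort",
    "ewas_to_table",
    "RunConfig",
    "run_pipeline",
]

_NA = "."


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _header_lines(seed=None, inputs=()) -> list[str]:
    lines = [f"# twinewas v{__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    for p in inputs:
        lines.append(f"# input sha256({Path(p).name})={_sha256(p)}")
    return lines


def write_table(df: pd.DataFrame, path, seed=None, inputs=(), index=True) -> None:
    """Write a TSV with a provenance header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _header_lines(seed, inputs):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", na_rep=_NA, index=index)


def read_table(path, **kwargs) -> pd.DataFrame:
    """Read a TSV/CSV (optionally gzipped), skipping '#' comment lines."""
    sep = kwargs.pop("sep", "\t")
    return pd.read_csv(path, sep=sep, comment="#", na_values=[_NA], **kwargs)


def read_methylation(
    path,
    annotation=None,
    detection_p=None,
    beads=None,
    intensity=None,
) -> MethylationMatrix:
    """Read a CpG x sample beta matrix (first column CpG id) plus sidecars.

    Values outside [0, 1] are rejected with the offending cell's
    coordinates; duplicated ids, ragged rows, and non-numeric cells raise.
    """

    def _read_matrix(p):
        df = read_table(p, index_col=0)
        try:
            return df.astype(float)
        except ValueError as exc:
            raise ValueError(f"non-numeric cell in {p}: {exc}") from exc

    beta = _read_matrix(path)
    ann = read_annotation(annotation) if annotation is not None else None
    return MethylationMatrix(
        beta=beta,
        annotation=ann,
        detection_p=_read_matrix(detection_p) if detection_p else None,
        beads=_read_matrix(beads) if beads else None,
        intensity=_read_matrix(intensity) if intensity else None,
    )


def read_annotation(path) -> pd.DataFrame:
    """CpG annotation: 4-column TSV (cpg_id, chrom, pos, gene) or BED.

    BED input (detected by a .bed suffix) is converted from 0-based
    half-open starts to 1-based positions; the BED name column is the CpG id.
    """
    path = Path(path)
    if path.suffix.lower() == ".bed" or path.name.lower().endswith(".bed.gz"):
        bed = read_table(
            path, header=None, names=["chrom", "start", "end", "cpg_id"]
        )
        ann = pd.DataFrame(
            {
                "chrom": bed["chrom"].astype(str).to_numpy(),
                "pos": bed["start"].astype(int).to_numpy() + 1,
                "gene": "",
            },
            index=pd.Index(bed["cpg_id"].to_numpy(), name="cpg_id"),
        )
        return ann
    ann = read_table(path)
    required = {"cpg_id", "chrom", "pos"}
    if not required <= set(ann.columns):
        raise ValueError(f"annotation must have columns {sorted(required)}")
    if "gene" not in ann.columns:
        ann["gene"] = ""
    ann["gene"] = ann["gene"].fillna("")
    ann["chrom"] = ann["chrom"].astype(str)
    ann["pos"] = ann["pos"].astype(int)
    return ann.set_index("cpg_id")


def read_gwas_hits(path) -> pd.DataFrame:
    """GWAS hits from a 3-column TSV: chrom, pos, pvalue."""
    hits = read_table(path)
    if not {"chrom", "pos", "pvalue"} <= set(hits.columns):
        hits = read_table(path, header=None, names=["chrom", "pos", "pvalue"])
    hits["chrom"] = hits["chrom"].astype(str)
    hits["pos"] = hits["pos"].astype(int)
    hits["pvalue"] = hits["pvalue"].astype(float)
    if (hits["pos"] <= 0).any():
        raise ValueError("GWAS hit positions must be positive (1-based)")
    if ((hits["pvalue"] <= 0) | (hits["pvalue"] > 1)).any():
        raise ValueError("GWAS p-values must be in (0, 1]")
    return hits


def read_sample_sheet(path) -> pd.DataFrame:
    from .preprocess import validate_sample_sheet

    return validate_sample_sheet(read_table(path))


def write_cohort(outdir, matrix, sheet, pairs, truth=None, seed=None) -> dict:
    """Write a (synthetic) cohort as delimited text files; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _w(name, df, index):
        p = outdir / name
        write_table(df, p, seed=seed, index=index)
        paths[name] = str(p)

    _w("beta.tsv", matrix.beta, True)
    if matrix.detection_p is not None:
        _w("detection_p.tsv", matrix.detection_p, True)
    if matrix.beads is not None:
        _w("beads.tsv", matrix.beads, True)
    if matrix.intensity is not None:
        _w("intensity.tsv", matrix.intensity, True)
    if matrix.annotation is not None:
        _w("annotation.tsv", matrix.annotation, True)
    _w("samples.tsv", sheet, False)
    _w("pairs.tsv", pairs.table, False)
    if truth is not None:
        _w("truth_cpg.tsv", truth.cpg, True)
        _w("truth_sample.tsv", truth.sample, True)
    return paths


def ewas_to_table(result: pd.DataFrame, annotation: pd.DataFrame | None) -> pd.DataFrame:
    """Shape an EWAS result for output: annotation columns + test columns."""
    out = result.copy()
    if annotation is not None:
        ann = annotation.reindex(out.index)
        for col in ("gene", "pos", "chrom"):
            if col in ann.columns:
                out.insert(0, col, ann[col])
    out.index.name = "cpg_id"
    return out


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of an end-to-end pipeline run."""

    out_dir: str = "twinewas_out"
    seed: int = 0
    # input paths; when beta is None a synthetic cohort is generated
    beta: str | None = None
    detection_p: str | None = None
    beads: str | None = None
    intensity: str | None = None
    annotation: str | None = None
    sample_sheet: str | None = None
    gwas: str | None = None
    simulate: dict = field(default_factory=dict)
    covariates: tuple = DEFAULT_COVARIATES
    alpha: float = 0.05
    detection_p_max: float = 0.01
    bead_min: int = 3
    success_min: float = 0.95
    top_k: int = 1000
    enrichment_window: int = 1_000_000
    enrichment_sig: float = 5e-8
    n_boot: int = 2000
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = (
            json.loads(text)
            if str(path).endswith(".json")
            else yaml.safe_load(text)
        )
        return cls(**data)

    def validate(self) -> None:
        if self.beta is None and not self.simulate and self.sample_sheet is None:
            # pure-default simulation is allowed
            pass
        for name in ("beta", "detection_p", "beads", "intensity", "annotation",
                     "sample_sheet", "gwas"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config input {name!r} not found: {p}")


def run_pipeline(config: RunConfig) -> dict:
    """Run filter -> residualize -> classify -> per-group EWAS ->
    reversibility -> dose-response -> enrichment; write TSVs and a manifest.

    Any stage failure aborts with the stage name; outputs written so far are
    preserved.  Returns a result bundle (in-memory objects + manifest).
    """
    from .dose_response import (
        dose_response_correlations,
        time_since_quit_correlation,
        twin_correlation,
        within_pair_delta,
    )
    from .enrichment import bootstrap_se, flag_proximal_cpgs
    from .ewas import inflation_lambda, paired_ewas, rank_by_p, within_pair_differences
    from .reversibility import group_difference_profile, ordering_check, percent_reduction
    from .synthetic import CohortConfig, generate_cohort

    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = [p for p in (config.beta, config.sample_sheet, config.gwas) if p]
    manifest: dict = {
        "tool": "twinewas",
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "alpha": config.alpha,
            "detection_p_max": config.detection_p_max,
            "bead_min": config.bead_min,
            "success_min": config.success_min,
            "enrichment_window": config.enrichment_window,
            "enrichment_sig": config.enrichment_sig,
            "n_boot": config.n_boot,
            "top_k": config.top_k,
        },
        "inputs": {str(p): _sha256(p) for p in inputs},
        "stages": {},
    }
    bundle: dict = {"manifest": manifest}

    def stage(name):
        logger.info("stage %s", name)

        class _Ctx:
            def __enter__(self):
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    _write_manifest()
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                return False

        return _Ctx()

    def _write_manifest():
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    with stage("load"):
        if config.beta is not None:
            matrix = read_methylation(
                config.beta,
                annotation=config.annotation,
                detection_p=config.detection_p,
                beads=config.beads,
                intensity=config.intensity,
            )
            sheet = read_sample_sheet(config.sample_sheet)
            truth = None
        else:
            sim = dict(config.simulate)
            sim.setdefault("seed", config.seed)
            matrix, sheet, _, truth = generate_cohort(CohortConfig.from_dict(sim))
        manifest["stages"]["load"] = {
            "n_cpgs": int(matrix.beta.shape[0]),
            "n_samples": int(matrix.beta.shape[1]),
        }

    with stage("filter"):
        rules_available = matrix.detection_p is not None
        if rules_available:
            matrix, report = filter_probes(
                matrix,
                detection_p_max=config.detection_p_max,
                bead_min=config.bead_min if matrix.beads is not None else None,
                success_min=config.success_min,
                drop_zero_intensity=matrix.intensity is not None,
            )
            manifest["stages"]["filter"] = {
                "n_detection_failed": report.n_detection_failed,
                "n_bead_failed": report.n_bead_failed,
                "n_zero_intensity": report.n_zero_intensity,
                "n_probes_dropped": report.n_probes_dropped,
                "n_samples_dropped": report.n_samples_dropped,
                "n_cpgs": int(matrix.beta.shape[0]),
                "n_samples": int(matrix.beta.shape[1]),
            }
        else:
            manifest["stages"]["filter"] = {
                "skipped": "no QC companion matrices",
                "n_cpgs": int(matrix.beta.shape[0]),
                "n_samples": int(matrix.beta.shape[1]),
            }

    with stage("classify"):
        sheet = sheet[sheet["sample_id"].isin(matrix.sample_ids)]
        pairs = classify_pairs(sheet)
        # keep only pairs with both members surviving filtering
        ok = pairs.table["sample_id_a"].isin(matrix.sample_ids) & pairs.table[
            "sample_id_b"
        ].isin(matrix.sample_ids)
        pairs = PairTable(table=pairs.table[ok].reset_index(drop=True),
                          exclusions=pairs.exclusions)
        counts = pairs.group_counts()
        manifest["stages"]["classify"] = {
            "group_counts": {k: int(v) for k, v in counts.items()},
            "n_excluded": int(len(pairs.exclusions)),
        }
        write_table(pairs.table, out / "pairs.tsv", seed=config.seed,
                    inputs=inputs, index=False)

    with stage("residualize"):
        resid = residualize(matrix, sheet, config.covariates)
        manifest["stages"]["residualize"] = {
            "covariates": list(config.covariates),
            "design_columns": list(resid.design_columns),
            "n_cpgs": int(resid.values.shape[0]),
        }

    with stage("ewas"):
        ewas_by_group: dict[str, pd.DataFrame] = {}
        diffs_by_group: dict[str, pd.DataFrame] = {}
        for group in GROUPS:
            if len(pairs.pairs_in_group(group)) < 2:
                continue
            diffs = within_pair_differences(resid, pairs, group)
            result = paired_ewas(diffs, alpha=config.alpha)
            diffs_by_group[group] = diffs
            ewas_by_group[group] = result
            write_table(
                ewas_to_table(rank_by_p(result), matrix.annotation),
                out / f"ewas_{group}.tsv",
                seed=config.seed,
                inputs=inputs,
            )
        primary = "discordant_current_never"
        if primary not in ewas_by_group:
            raise ValueError("no current/never discordant pairs; cannot run the EWAS")
        res = ewas_by_group[primary]
        tested = res.loc[~res["degenerate"]]
        infl = inflation_lambda(tested["t"], df=tested["n_pairs"].iloc[0] - 1)
        manifest["stages"]["ewas"] = {
            "groups": {
                g: {
                    "n_pairs": int(d.shape[1]),
                    "n_cpgs_tested": int(r.attrs["m_tested"]),
                    "n_significant": int(r["significant"].sum()),
                    "bonferroni_threshold": float(r.attrs["bonferroni_threshold"]),
                }
                for g, (d, r) in (
                    (g, (diffs_by_group[g], ewas_by_group[g])) for g in ewas_by_group
                )
            },
            "inflation": {
                "lambda": infl.lam,
                "z_mean": infl.z_mean,
                "z_sd": infl.z_sd,
            },
        }
        bundle["ewas"] = ewas_by_group
        bundle["diffs"] = diffs_by_group
        bundle["inflation"] = infl

    with stage("reversibility"):
        sig = res.index[res["significant"]]
        top = rank_by_p(res).index[: min(len(sig) if len(sig) else 13, len(res))]
        cpg_set = sig if len(sig) else top
        rev = None
        if "discordant_former_never" in ewas_by_group and len(cpg_set):
            rev = percent_reduction(
                res, ewas_by_group["discordant_former_never"], cpg_set
            )
            write_table(rev["table"], out / "reversibility.tsv",
                        seed=config.seed, inputs=inputs)
        profile = group_difference_profile(
            diffs_by_group, res, top_k=min(config.top_k, len(res))
        )
        ordering = ordering_check(profile)
        write_table(profile, out / "group_profile.tsv", seed=config.seed, inputs=inputs)
        manifest["stages"]["reversibility"] = {
            "cpg_set": list(cpg_set),
            "mean_reduction_pct": None if rev is None else rev["mean"],
            "ordering": ordering,
        }
        bundle["reversibility"] = rev
        bundle["profile"] = profile
        bundle["ordering"] = ordering

    with stage("dose_response"):
        dr = None
        if "concordant_current" in diffs_by_group and len(cpg_set):
            deltas = pd.DataFrame(
                {
                    "cpd": within_pair_delta(
                        sheet, pairs, "cigarettes_per_day", "concordant_current"
                    ),
                    "packyears": within_pair_delta(
                        sheet, pairs, "packyears", "concordant_current"
                    ),
                    "cotinine": within_pair_delta(
                        sheet, pairs, "cotinine", "concordant_current"
                    ),
                }
            )
            dr = dose_response_correlations(
                diffs_by_group["concordant_current"].loc[cpg_set], deltas
            )
            write_table(dr, out / "dose_response.tsv", seed=config.seed, inputs=inputs)
            tw = twin_correlation(sheet, pairs, "cigarettes_per_day", "concordant_current")
            manifest["stages"]["dose_response"] = {
                "summary": dr.attrs["summary"],
                "twin_r_cpd": tw,
            }
            bundle["dose_response"] = dr
            bundle["twin_correlation"] = tw
        tsq = None
        if "discordant_former_never" in diffs_by_group and len(cpg_set):
            fn_pairs = pairs.pairs_in_group("discordant_former_never")
            yq = (
                sheet.set_index("sample_id")["years_since_quit"]
                .reindex(fn_pairs["exposed_member"])
                .set_axis(fn_pairs["pair_id"])
            )
            tsq = time_since_quit_correlation(
                diffs_by_group["discordant_former_never"].loc[cpg_set], yq
            )
            write_table(tsq, out / "time_since_quit.tsv", seed=config.seed, inputs=inputs)
            bundle["time_since_quit"] = tsq

    with stage("enrichment"):
        enr = None
        if config.gwas is not None:
            if matrix.annotation is None:
                raise ValueError("enrichment requires CpG annotation")
            hits = read_gwas_hits(config.gwas)
            flag = flag_proximal_cpgs(
                matrix.annotation.loc[tested.index],
                hits,
                window=config.enrichment_window,
                sig=config.enrichment_sig,
            )
            enr = bootstrap_se(
                tested["t"].abs().to_numpy(),
                flag.to_numpy(),
                n_boot=config.n_boot,
                seed=config.seed,
            )
            manifest["stages"]["enrichment"] = {
                "beta_gwaslocus": enr.beta_gwaslocus,
                "se": enr.se,
                "p": enr.p,
                "n_flagged": enr.n_flagged,
                "n_total": enr.n_total,
                "n_boot": enr.n_boot,
            }
            bundle["enrichment"] = enr

    _write_manifest()
    bundle["out_dir"] = str(out)
    return bundle
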