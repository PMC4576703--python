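"""End-to-end orchestration: filter -> classify -> statistics -> flank
profiles -> LD decay -> export files, from a single validated config.

The pipeline is deterministic for a fixed config: every stochastic step
(bootstrap, LD pair subsampling) draws from a named substream of the root
seed. All outputs land in ``out_dir`` and are listed in ``manifest.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .variant_io import (
    FilterConfig, apply_site_filters, compute_modal_coverage, cpg_prone_mask,
    depth_histograms, indel_mask, proximity_filter, read_vcf, CallabilityMask,
)
from .site_classes import (
    CLASS_CODES, SiteClassMap, assign_intervals, build_cne_flank_reference,
    build_cne_sets, classify_degeneracy, read_bed_intervals,
    read_gff3_transcripts, write_class_bed,
)
from .popgen_stats import (
    ClassSummary, NeEstimate, bootstrap_ci, encode_psmc_input, estimate_mu,
    estimate_ne, project_folded_sfs, site_pi, tajimas_d_from_sfs,
    write_dfe_alpha_sfs,
)
from .flank_profile import (
    bin_flank_statistics, cne_exon_distance_kernel, convolve_profile,
    fit_far_slope,
)
from .ld_decay import (
    fit_offset_exponential, fit_stretched_exponential, ld_decay_curve,
    theoretical_r2_floor,
)

__all__ = ["RunConfig", "validate_config", "run_pipeline"]

ANALYSIS_CLASSES = ("fold0", "fold2", "fold4", "cne", "cne_flank")


@dataclass
class RunConfig:
    vcf: str
    reference: str
    outgroup: str
    gff3: str
    cne_bed: str
    out_dir: str = "pipeline_out"
    filters: FilterConfig = field(default_factory=FilterConfig)
    cne_variant: str = "noOverlap_lt1kb"
    n_proj: int = 6
    n_boot: int = 1000
    boot_window_bp: int = 1_000_000
    exon_flank_bin: int = 1000
    exon_flank_max: int = 100_000
    cne_flank_bin: int = 100
    cne_flank_max: int = 5000
    ld_max_distance: int = 40_000
    ld_bin: int = 20
    ld_n_max: int = 750
    ld_fix_d: float = 0.5
    t_split_years: float = 1.2e7
    gens_per_year: float = 2.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["filters"] = dataclasses.asdict(self.filters)
        return d


def validate_config(config: RunConfig) -> list[str]:
    """Collect ALL validation problems (empty list = ok)."""
    errors: list[str] = []
    for name in ("vcf", "reference", "outgroup", "gff3", "cne_bed"):
        p = getattr(config, name)
        if not p or not Path(p).exists():
            errors.append(f"input file missing: {name}={p!r}")
    f = config.filters
    if f.proximity_md < 0:
        errors.append("proximity_md >= 0 required")
    if f.per_sample_cov_bounds[0] > f.per_sample_cov_bounds[1]:
        errors.append("per_sample_cov_bounds out of order")
    if f.mean_cov_bounds[0] > f.mean_cov_bounds[1]:
        errors.append("mean_cov_bounds out of order")
    if config.n_proj < 4:
        errors.append("n_proj >= 4 required")
    if config.cne_variant not in ("noOverlap", "strict", "noOverlap_lt1kb"):
        errors.append(f"unknown cne_variant {config.cne_variant!r}")
    if config.ld_fix_d is not None and not (0 < config.ld_fix_d <= 1):
        errors.append("ld_fix_d must be in (0, 1]")
    for name in ("exon_flank_bin", "cne_flank_bin", "ld_bin",
                 "ld_max_distance", "ld_n_max"):
        if getattr(config, name) < 1:
            errors.append(f"{name} >= 1 required")
    if config.n_boot < 0:
        errors.append("n_boot >= 0 required")
    return errors


def _read_fasta_single(path) -> str:
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    name = list(fa.keys())[0]
    return str(fa[name][:]).upper()


def _substream(root_seed: int, name: str) -> int:
    h = hashlib.sha256(f"{root_seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the report bundle (also written to
    ``out_dir``). Raises with the stage name on any stage failure."""
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    log: dict = {"stages": {}}

    stage = "read_inputs"
    try:
        reference = _read_fasta_single(config.reference)
        outgroup = _read_fasta_single(config.outgroup)
        records, indels, samples = read_vcf(config.vcf)
        transcripts = read_gff3_transcripts(config.gff3)
        raw_cnes = read_bed_intervals(config.cne_bed)
        L = len(reference)

        stage = "filter"
        coverage = compute_modal_coverage(depth_histograms(records)) if records \
            else None
        mask = CallabilityMask(n_considered=L)
        for chrom, ivs in indel_mask(indels).items():
            for lo, hi in ivs:
                for p in range(lo, min(hi, L) + 1):
                    mask.fail(p, "indel")
        if config.filters.cpg_exclude:
            cpg = cpg_prone_mask(reference, outgroup)
            for p in np.nonzero(cpg)[0]:
                mask.fail(int(p) + 1, "cpg")
        passed, mask = apply_site_filters(records, coverage, config.filters, mask) \
            if records else ([], mask)
        if config.filters.proximity_md > 0 and passed:
            pos = np.array([r.pos for r in passed])
            kept = set(proximity_filter(pos, config.filters.proximity_md).tolist())
            for r in passed:
                if r.pos not in kept:
                    mask.fail(r.pos, "proximity")
            passed = [r for r in passed if r.pos in kept]
        log["stages"]["filter"] = {
            "n_records_in": len(records), "n_pass": len(passed),
            "n_fail": mask.n_fail,
            "fail_reasons": _reason_counts(mask),
        }

        stage = "classify"
        site_map = SiteClassMap.empty(L)
        classify_degeneracy(transcripts, reference, site_map)
        exon_iv = [(s, e) for t in transcripts for s, e in t.cds]
        cne_set = build_cne_sets(raw_cnes, exon_iv, config.cne_variant)
        cne_full = build_cne_sets(raw_cnes, exon_iv, "noOverlap")
        flanks = build_cne_flank_reference(cne_set, exon_iv, cne_full, L)
        assign_intervals(site_map, cne_set.intervals, "cne")
        assign_intervals(site_map, flanks, "cne_flank")
        write_class_bed(site_map, out / "site_classes.bed")
        outputs["site_classes"] = str(out / "site_classes.bed")
        log["stages"]["classify"] = site_map.summary()

        stage = "stats"
        accessible = mask.pass_array(L)
        ref_arr = np.frombuffer(reference.encode(), dtype="S1")
        out_arr = np.frombuffer(outgroup.encode(), dtype="S1")
        major = ref_arr.copy()
        pi_site = np.zeros(L)
        j_site = np.full(L, -1, dtype=np.int32)
        n_site = np.zeros(L, dtype=np.int32)
        for r in passed:
            p0 = r.pos - 1
            called = r.genotypes >= 0
            n_al = 2 * int(called.sum())
            if n_al < 2:
                continue
            alt = int(r.genotypes[called].sum())
            j = min(alt, n_al - alt)
            pi_site[p0] = site_pi(j, n_al)
            j_site[p0] = j
            n_site[p0] = n_al
            if 2 * alt > n_al and r.alt_alleles:
                major[p0] = r.alt_alleles[0].encode()
        div_site = (major != out_arr) & (out_arr != b"N")
        has_out = out_arr != b"N"

        summaries, sfs_by_class = _class_summaries(
            config, site_map, accessible, pi_site, j_site, n_site,
            div_site, has_out, transcripts, L,
        )
        ne_est = _ne_estimate(config, summaries)
        _write_summaries(out, summaries, ne_est, outputs)

        stage = "flanks"
        flank_out = _flank_stage(config, out, outputs, site_map, accessible,
                                 pi_site, div_site, has_out, exon_iv,
                                 cne_full, L)

        stage = "ld"
        ld_out = _ld_stage(config, out, outputs, passed, site_map)

        stage = "exports"
        # PSMC-style encoding for the first sample
        if passed and samples:
            het = np.zeros(L, dtype=bool)
            called0 = accessible.copy()
            for r in passed:
                g = r.genotypes[0]
                if g == 1:
                    het[r.pos - 1] = True
                elif g < 0:
                    called0[r.pos - 1] = False
            psmc_text = encode_psmc_input(het, called0)
            (out / "sample0.psmcfa").write_text(psmc_text)
            outputs["psmcfa"] = str(out / "sample0.psmcfa")
        if "fold0" in sfs_by_class and "fold4" in sfs_by_class:
            divs = {
                c: (s.d if s.d is not None else 0.0, s.n_sites)
                for c, s in ((c, x) for c, x in
                             zip([s.class_name for s in summaries], summaries))
                if c in ("fold0", "fold4")
            }
            write_dfe_alpha_sfs(sfs_by_class["fold0"], sfs_by_class["fold4"],
                                divs, out / "dfe_sfs.txt")
            outputs["dfe_sfs"] = str(out / "dfe_sfs.txt")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "inputs": {k: getattr(config, k)
                   for k in ("vcf", "reference", "outgroup", "gff3", "cne_bed")},
        "seed": config.seed,
        "outputs": outputs,
        "log": log,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    bundle = {
        "summaries": summaries,
        "ne_estimate": ne_est,
        "flanks": flank_out,
        "ld": ld_out,
        "manifest": manifest,
        "mask": mask,
        "site_map": site_map,
    }
    return bundle


def _reason_counts(mask: CallabilityMask) -> dict[str, int]:
    counts: dict[str, int] = {}
    for reason in mask.reasons.values():
        counts[reason] = counts.get(reason, 0) + 1
    return counts


def _class_summaries(config, site_map, accessible, pi_site, j_site, n_site,
                     div_site, has_out, transcripts, L):
    summaries: list[ClassSummary] = []
    sfs_by_class: dict = {}
    for cls in ANALYSIS_CLASSES:
        pos = site_map.positions_of(cls)
        pos = pos[accessible[pos]]
        n_acc = pos.size
        if n_acc == 0:
            continue
        pi = float(pi_site[pos].sum() / n_acc)
        d_pos = pos[has_out[pos]]
        d = float(div_site[d_pos].mean()) if d_pos.size else None
        seg = pos[(j_site[pos] > 0)]
        n_mono = n_acc - seg.size
        sfs = project_folded_sfs(j_site[seg], n_site[seg], config.n_proj,
                                 n_monomorphic=n_mono, class_label=cls)
        sfs_by_class[cls] = sfs
        try:
            taj = tajimas_d_from_sfs(sfs)
        except ValueError:
            taj = None
        ci = {}
        units = _boot_units(cls, pos, transcripts, config.boot_window_bp, L)
        if len(units) >= 2 and config.n_boot > 0:
            def pi_stat(us):
                all_pos = np.concatenate(us) if us else np.empty(0, dtype=int)
                if all_pos.size == 0:
                    raise ValueError("empty resample")
                return float(pi_site[all_pos].sum() / all_pos.size)
            try:
                ci["pi"] = bootstrap_ci(
                    pi_stat, units, n_boot=config.n_boot,
                    seed=_substream(config.seed, f"boot:{cls}"),
                )
            except ValueError:
                pass
        summaries.append(ClassSummary(
            class_name=cls, n_sites=int(n_acc), pi=pi, d=d,
            pi_over_d=(pi / d if d else None), tajima_d=taj, ci_95=ci,
        ))
    return summaries, sfs_by_class


def _boot_units(cls, pos, transcripts, window_bp, L):
    """Resampling units: transcripts for exonic classes, nonempty windows
    for CNE classes."""
    if cls.startswith("fold"):
        units = []
        for t in transcripts:
            if t.valid is False:
                continue
            tp = np.concatenate([np.arange(s, e) for s, e in t.cds])
            u = np.intersect1d(tp, pos)
            if u.size:
                units.append(u)
        return units
    units = []
    for w0 in range(0, L, window_bp):
        u = pos[(pos >= w0) & (pos < w0 + window_bp)]
        if u.size:
            units.append(u)
    return units


def _ne_estimate(config, summaries):
    by = {s.class_name: s for s in summaries}
    neutral = by.get("fold4") or by.get("cne_flank")
    if neutral is None or not neutral.d:
        return None
    mu = estimate_mu(neutral.d, config.t_split_years, config.gens_per_year)
    ne = estimate_ne(neutral.pi, mu)
    return NeEstimate(mu_hat=mu, ne_hat=ne, inputs={
        "class": neutral.class_name, "d": neutral.d, "pi": neutral.pi,
        "t_split_years": config.t_split_years,
        "gens_per_year": config.gens_per_year,
    })


def _write_summaries(out, summaries, ne_est, outputs):
    import pandas as pd

    rows = []
    for s in summaries:
        rows.append({
            "class": s.class_name, "n_sites": s.n_sites, "pi": s.pi,
            "d": s.d, "pi_over_d": s.pi_over_d, "tajima_d": s.tajima_d,
            "pi_ci_lo": s.ci_95.get("pi", (None, None))[0],
            "pi_ci_hi": s.ci_95.get("pi", (None, None))[1],
        })
    pd.DataFrame(rows).to_csv(out / "class_summary.tsv", sep="\t", index=False)
    outputs["class_summary"] = str(out / "class_summary.tsv")
    if ne_est is not None:
        (out / "ne_estimate.json").write_text(json.dumps({
            "mu_hat": ne_est.mu_hat, "ne_hat": ne_est.ne_hat,
            "inputs": ne_est.inputs,
        }, indent=1))
        outputs["ne_estimate"] = str(out / "ne_estimate.json")


def _eligible_flank_sites(site_map, accessible):
    codes = site_map.codes
    ok = accessible & (codes != CLASS_CODES["fold0"]) \
        & (codes != CLASS_CODES["fold2"]) & (codes != CLASS_CODES["fold4"]) \
        & (codes != CLASS_CODES["cne"])
    return np.nonzero(ok)[0]


def _flank_stage(config, out, outputs, site_map, accessible, pi_site,
                 div_site, has_out, exon_iv, cne_full, L):
    sites = _eligible_flank_sites(site_map, accessible)
    div_vals = np.where(has_out[sites], div_site[sites].astype(float), np.nan)
    result = {}
    if exon_iv:
        prof = bin_flank_statistics(
            sites, pi_site[sites], div_vals, exon_iv,
            config.exon_flank_bin, config.exon_flank_max, "exon")
        prof.to_tsv(out / "exon_flanks.tsv")
        outputs["exon_flanks"] = str(out / "exon_flanks.tsv")
        result["exon"] = prof
    if cne_full.intervals:
        prof_c = bin_flank_statistics(
            sites, pi_site[sites], div_vals, cne_full.intervals,
            config.cne_flank_bin, config.cne_flank_max, "cne")
        prof_c.to_tsv(out / "cne_flanks.tsv")
        outputs["cne_flanks"] = str(out / "cne_flanks.tsv")
        result["cne"] = prof_c
        try:
            result["cne_slope"] = fit_far_slope(
                prof_c, (5000, min(20000, config.cne_flank_max)))
        except ValueError:
            pass
    if exon_iv and cne_full.intervals:
        try:
            kernel = cne_exon_distance_kernel(cne_full.intervals, exon_iv,
                                              cap=min(200_000, L))
            fine = bin_flank_statistics(
                sites, pi_site[sites], div_vals, exon_iv, 100,
                config.exon_flank_max, "exon")
            pad_bins = (min(600, fine.n_bins // 2), min(1000, fine.n_bins))
            blurred = convolve_profile(
                fine.table["pi"].to_numpy(), kernel, pad_range_bins=pad_bins)
            result["kernel"] = kernel
            result["blurred_exon_pi"] = blurred
            np.savetxt(out / "blurred_exon_pi.tsv", blurred)
            outputs["blurred_exon_pi"] = str(out / "blurred_exon_pi.tsv")
        except ValueError:
            pass
    return result


def _ld_stage(config, out, outputs, passed, site_map):
    snv_pos = np.array([r.pos - 1 for r in passed], dtype=np.int64)
    if snv_pos.size < 2:
        return {}
    G = np.stack([r.genotypes for r in passed], axis=1)
    result = {}
    codes = site_map.codes
    focal_sets = {
        "all": None,
        "exon": snv_pos[np.isin(codes[snv_pos],
                                [CLASS_CODES["fold0"], CLASS_CODES["fold2"],
                                 CLASS_CODES["fold4"]])],
        "cne": snv_pos[codes[snv_pos] == CLASS_CODES["cne"]],
    }
    for name, focal in focal_sets.items():
        if focal is not None and focal.size == 0:
            continue
        curve = ld_decay_curve(
            G, snv_pos, focal, max_distance=config.ld_max_distance,
            bin_bp=config.ld_bin, n_max=config.ld_n_max,
            seed=_substream(config.seed, f"ld:{name}"), focal_set=name)
        curve.to_tsv(out / f"ld_{name}.tsv")
        outputs[f"ld_{name}"] = str(out / f"ld_{name}.tsv")
        fits = {}
        try:
            fits["exp"] = fit_offset_exponential(curve)
            fits["stretched"] = fit_stretched_exponential(curve)
            fits["stretched_d05"] = fit_stretched_exponential(
                curve, fix_d=config.ld_fix_d)
        except ValueError:
            pass
        (out / f"ld_{name}_fits.json").write_text(json.dumps(
            {k: f.to_dict() for k, f in fits.items()}, indent=1))
        outputs[f"ld_{name}_fits"] = str(out / f"ld_{name}_fits.json")
        result[name] = {"curve": curve, "fits": fits,
                        "floor": theoretical_r2_floor(G.shape[0])}
    return result
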