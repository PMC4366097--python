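"""End-to-end orchestration: simulate -> process -> correlate -> biopsy.

One run emulates a small patient cohort: per subject a phantom is built from
a subject-specific seed, acquired, processed to a B0-corrected MTR_asym map,
correlated voxelwise with ADC inside the cleaned ROIs (one Table-1-style row
per ROI), and sampled along a stereotactic trajectory for the biopsy
correlation (one Table-2-style row).  A JSON manifest records seeds,
per-stage voxel bookkeeping and the output files; re-running with the same
seed reproduces every table bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, biopsy as bx, io, region_stats as rs, zspec
from .phantom import (
    AcquisitionParams,
    PhantomConfig,
    Tissue,
    build_phantom,
    default_trajectory,
    simulate_acquisition,
    simulate_biopsy_set,
)


@dataclass
class AnalysisOptions:
    """Processing and statistics settings shared by all subjects."""

    alpha: float = 0.05
    readout_ppm: float = zspec.READOUT_PPM
    b0_search_halfwidth_ppm: float = 1.0
    bands: tuple[float, float, float] = rs.DEFAULT_BANDS
    swi_exclusion_fraction: float = 0.02

    def __post_init__(self) -> None:
        lo, mid, hi = self.bands
        if not 0 < lo < mid < hi:
            raise ValueError("classification bands must be strictly ordered")


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    seed: int = 0
    n_patients: int = 3
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(str(path)).read_text()) or {}
        kwargs = {}
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        if "n_patients" in raw:
            kwargs["n_patients"] = int(raw["n_patients"])
        if "phantom" in raw:
            ph = dict(raw["phantom"])
            for key in ("shape", "voxel_size_mm", "brain_semiaxes_mm",
                        "tumor_center_mm", "edema_semiaxes_mm"):
                if key in ph:
                    ph[key] = tuple(ph[key])
            for key in ("noe_amplitude", "adc_mean", "cell_mean", "rho_cell", "rho_adc"):
                if key in ph:
                    ph[key] = {Tissue[k.upper()]: float(v) for k, v in ph[key].items()}
            kwargs["phantom"] = PhantomConfig(**ph)
        if "acquisition" in raw:
            ac = dict(raw["acquisition"])
            if "offsets_ppm" in ac:
                ac["offsets_ppm"] = tuple(ac["offsets_ppm"])
            kwargs["acquisition"] = AcquisitionParams(**ac)
        if "analysis" in raw:
            an = dict(raw["analysis"])
            if "bands" in an:
                an["bands"] = tuple(an["bands"])
            kwargs["analysis"] = AnalysisOptions(**an)
        return cls(**kwargs)


def swi_exclusion_mask(
    label_map: np.ndarray, fraction: float, seed: int
) -> np.ndarray:
    """Sparse random blob mask standing in for SWI hypointensities.

    Seeds a few voxels inside the tumor+edema region and dilates them by one
    voxel, removing roughly ``fraction`` of the lesion voxels.
    """
    rng = np.random.default_rng(seed)
    lesion = np.isin(label_map, (Tissue.EDEMA, Tissue.CE_TUMOR, Tissue.NECROSIS))
    mask = np.zeros_like(lesion)
    n_target = int(fraction * lesion.sum())
    if n_target == 0:
        return mask
    cand = np.argwhere(lesion)
    picks = cand[rng.choice(len(cand), size=max(1, n_target // 7), replace=False)]
    for i, j, k in picks:
        sl = tuple(slice(max(0, c - 1), c + 2) for c in (i, j, k))
        mask[sl] = True
    return mask & lesion


def process_subject(phantom, acquisition, analysis: AnalysisOptions):
    """Acquisition arrays -> B0-corrected MTR_asym map (plus intermediates)."""
    z = zspec.normalize(
        acquisition.saturated, acquisition.m0, acquisition.offsets_ppm, acquisition.affine
    )
    b0 = zspec.estimate_b0(z, search_halfwidth_ppm=analysis.b0_search_halfwidth_ppm)
    zc = zspec.correct_b0(z, b0)
    mtr = zspec.compute_mtr_asym(zc, readout_ppm=analysis.readout_ppm)
    return z, b0, zc, mtr


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the full synthetic study and write all outputs to ``out_dir``.

    Returns the manifest (also written as manifest.json).  On any stage
    failure, partial outputs are removed and the error re-raised with the
    stage name.
    """
    out = Path(str(out_dir))
    out.mkdir(parents=True, exist_ok=True)
    created = True
    stage = "setup"
    try:
        ss = np.random.SeedSequence(config.seed)
        subject_seeds = [int(s) for s in ss.generate_state(3 * config.n_patients) % (2**31)]
        results: list[rs.CorrelationResult] = []
        biopsy_rows = []
        manifest: dict = {
            "version": __version__,
            "seed": config.seed,
            "n_patients": config.n_patients,
            "subjects": {},
            "outputs": [],
        }
        for p in range(config.n_patients):
            pid = f"sim{p + 1:02d}"
            s_phantom, s_acq, s_bio = subject_seeds[3 * p : 3 * p + 3]
            stage = f"{pid}:simulate"
            ph_cfg = dataclasses.replace(config.phantom, seed=s_phantom)
            phantom = build_phantom(ph_cfg)
            acq = simulate_acquisition(phantom, config.acquisition, seed=s_acq)
            stage = f"{pid}:process"
            z, b0, zc, mtr = process_subject(phantom, acq, config.analysis)
            stage = f"{pid}:correlate"
            swi = swi_exclusion_mask(
                phantom.label_map, config.analysis.swi_exclusion_fraction, seed=s_bio + 1
            )
            rois = rs.RoiMaskSet(
                ce_t1_tumor=phantom.label_map == Tissue.CE_TUMOR,
                t2_edema=phantom.label_map == Tissue.EDEMA,
                swi_exclusion=swi,
                necrosis=phantom.label_map == Tissue.NECROSIS,
            )
            clean = rs.apply_exclusions(rois)
            pairs = rs.extract_pairs(mtr.values_percent, phantom.adc_map, clean)
            for roi in ("ce_t1_tumor", "t2_edema"):
                results.append(
                    rs.correlate_roi(
                        pairs, roi, patient=pid,
                        alpha=config.analysis.alpha, bands=config.analysis.bands,
                    )
                )
            stage = f"{pid}:biopsy"
            traj = default_trajectory(phantom)
            samples = simulate_biopsy_set(phantom, traj, seed=s_bio)
            samples = bx.read_out_biopsies(
                samples, mtr.values_percent, phantom.adc_map, phantom.affine,
                label_map=phantom.label_map,
            )
            bio = bx.correlate_biopsies(samples)
            biopsy_rows.append(
                {
                    "patient": pid,
                    "r_sp_mtr_cell": bio.r_sp_mtr_cell,
                    "p_mtr_cell": bio.p_mtr_cell,
                    "r_sp_adc_cell": bio.r_sp_adc_cell,
                    "p_adc_cell": bio.p_adc_cell,
                    "n_biopsies": bio.n_samples,
                    "max_cell_density": bio.max_cell_density,
                }
            )
            stage = f"{pid}:write"
            io.save_cest_stack(out / f"{pid}_cest.nii.gz", acq.saturated, acq.offsets_ppm, acq.affine)
            io.save_nifti(out / f"{pid}_m0.nii.gz", acq.m0, acq.affine)
            io.save_nifti(out / f"{pid}_adc.nii.gz", phantom.adc_map, acq.affine)
            io.save_nifti(out / f"{pid}_labels.nii.gz", phantom.label_map, acq.affine, dtype=np.uint8)
            io.save_nifti(out / f"{pid}_mtr_asym.nii.gz", mtr.values_percent, acq.affine)
            io.save_nifti(out / f"{pid}_b0_ppm.nii.gz", b0.delta_ppm, acq.affine)
            io.save_biopsy_csv(out / f"{pid}_biopsies.csv", samples)
            roi_sizes = {
                "ce_t1_tumor": int(rois.ce_t1_tumor.sum()),
                "t2_edema": int(rois.t2_edema.sum()),
            }
            clean_sizes = {
                "ce_t1_tumor": int(clean.ce_t1_tumor.sum()),
                "t2_edema": int(clean.t2_edema.sum()),
            }
            manifest["subjects"][pid] = {
                "seeds": {"phantom": s_phantom, "acquisition": s_acq, "biopsy": s_bio},
                "voxels": {
                    "mask": int(z.mask.sum()),
                    "b0_valid": int((b0.valid & z.mask).sum()),
                    "roi_total": roi_sizes,
                    "roi_after_exclusion": clean_sizes,
                    "roi_excluded": {
                        k: roi_sizes[k] - clean_sizes[k] for k in roi_sizes
                    },
                    "pairs_dropped_nonfinite": pairs.attrs["n_dropped"],
                    "pairs_used": {
                        k: int((pairs["roi"] == k).sum())
                        for k in ("ce_t1_tumor", "t2_edema")
                    },
                },
            }
        stage = "tables"
        summary = rs.summarize_cohort(results)
        table1 = summary.pop("cohort_table")
        table1.to_csv(out / "table1.csv", index=False)
        table2 = pd.DataFrame(biopsy_rows)
        table2.to_csv(out / "table2.csv", index=False)
        io.save_json(out / "cohort_summary.json", summary)
        manifest["outputs"] = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
        io.save_json(out / "manifest.json", manifest)
        return manifest
    except Exception as err:  # noqa: BLE001 - abort policy: clean partial outputs
        if created:
            for p in out.glob("*"):
                if p.is_file():
                    p.unlink()
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err


def render_report(out_dir) -> Path:
    """Markdown report with cohort counts and Fig-4/Fig-5-style scatterplots."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(str(out_dir))
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError("no manifest.json: run the pipeline first")
    import json

    manifest = json.loads(manifest_path.read_text())
    table1 = pd.read_csv(out / "table1.csv")
    table2 = pd.read_csv(out / "table2.csv")

    lines = ["# NOE-CEST synthetic cohort report", ""]
    lines.append(f"Package version {manifest['version']}, master seed {manifest['seed']}, "
                 f"{manifest['n_patients']} subjects.")
    lines.append("")
    lines.append("## Voxelwise MTR_asym vs ADC")
    lines.append("")
    lines.append(table1.to_markdown(index=False))
    lines.append("")
    for roi in ("ce_t1_tumor", "t2_edema"):
        sub = table1[table1["roi"] == roi]
        if sub.empty or (sub["n"] == 0).all():
            lines.append(f"ROI {roi}: empty after exclusions.")
            continue
        counts = sub["class"].value_counts().to_dict()
        lines.append(f"ROI {roi}: " + ", ".join(f"{v} {k}" for k, v in sorted(counts.items())))
    lines.append("")
    lines.append("## Biopsy cellularity correlations")
    lines.append("")
    lines.append(table2.to_markdown(index=False))
    lines.append("")

    # scatterplots per subject
    for pid in manifest["subjects"]:
        samples = pd.read_csv(out / f"{pid}_biopsies.csv")
        fig, ax = plt.subplots(1, 2, figsize=(8, 3.2))
        ax[0].scatter(samples["mtr_asym_mean_percent"], samples["cell_density_per_mm3"], s=18)
        ax[0].set_xlabel("MTR_asym (%)")
        ax[0].set_ylabel("cell density (1/mm^3)")
        ax[1].scatter(samples["adc_mean"], samples["cell_density_per_mm3"], s=18, color="tab:red")
        ax[1].set_xlabel("ADC (1e-6 mm^2/s)")
        fig.suptitle(f"{pid}: biopsy readout")
        fig.tight_layout()
        fig.savefig(out / f"{pid}_fig5.png", dpi=110)
        plt.close(fig)
        lines.append(f"![{pid} biopsy scatter]({pid}_fig5.png)")
    lines.append("")
    lines.append("## Outputs")
    lines.append("")
    for name in manifest["outputs"]:
        lines.append(f"- {name}")
    report = out / "report.md"
    report.write_text("\n".join(lines) + "\n")
    return report
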