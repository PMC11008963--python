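"""End-to-end orchestration: configuration, the full biting analysis
(8 simulations -> trim -> interval profiles -> PCA -> convergence -> region
contrasts), supplementary-table readers, and result bundles with manifests.

The supplementary readers accept tabular CSV exports of the study's
electronic supplementary files: site tables (S1 layout), interval-profile
tables (S3 layout) and per-element stress/volume tables (S4 layout).  Column
names can be remapped through configuration when an export uses different
headers.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fem import MaterialMap
from .intervals import (
    DEFAULT_CANDIDATES,
    DEFAULT_EPSILON,
    DEFAULT_TRIM_FRACTION,
    DEFAULT_UPPER_TAIL,
    ConvergenceTrace,
    IntervalProfile,
    PcaSummary,
    StressSample,
    build_profile,
    convergence_select,
    pca_profiles,
    sample_from_field,
    trim_top_stress,
)
from .mesh import LabeledMesh, read_mesh, write_mesh
from .scenarios import (
    DEFAULT_SCENARIOS,
    Scenario,
    normalize_stress,
    region_median_contrast,
    run_biting_suite,
)
from .stats import REGION_ORDER
from .synthetic import (
    MandibleParams,
    SiteTableParams,
    default_materials,
    generate_mandible_mesh,
    generate_site_table,
    read_site_table,
    write_site_table,
)

__all__ = [
    "RunConfig",
    "PipelineResult",
    "run_pipeline",
    "read_supplementary_table",
    "materials_from_dict",
]


def materials_from_dict(d: dict) -> MaterialMap:
    """{'MM': {'E_GPa': 6.0, 'nu': 0.3}, ...} -> MaterialMap."""
    return MaterialMap(
        {r: (float(v["E_GPa"]), float(v.get("nu", 0.3))) for r, v in d.items()}
    )


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    mesh_file: str | None = None
    mandible: MandibleParams = field(default_factory=MandibleParams)
    materials: MaterialMap = field(default_factory=default_materials)
    scenarios: tuple[Scenario, ...] = DEFAULT_SCENARIOS
    trim_fraction: float = DEFAULT_TRIM_FRACTION
    upper_tail: float = DEFAULT_UPPER_TAIL
    candidates: tuple[int, ...] = DEFAULT_CANDIDATES
    epsilon: float = DEFAULT_EPSILON
    scale_pca: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        if "mesh_file" in raw:
            kwargs["mesh_file"] = raw["mesh_file"]
        if "mandible" in raw:
            kwargs["mandible"] = MandibleParams(**raw["mandible"])
        if "materials" in raw:
            kwargs["materials"] = materials_from_dict(raw["materials"])
        if "scenarios" in raw:
            kwargs["scenarios"] = tuple(Scenario(**s) for s in raw["scenarios"])
        for key in ("trim_fraction", "upper_tail", "epsilon", "scale_pca", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "candidates" in raw:
            kwargs["candidates"] = tuple(int(c) for c in raw["candidates"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "mesh_file": self.mesh_file,
            "mandible": asdict(self.mandible),
            "materials": {
                r: {"E_GPa": E, "nu": nu} for r, (E, nu) in self.materials.properties.items()
            },
            "scenarios": [asdict(s) for s in self.scenarios],
            "trim_fraction": self.trim_fraction,
            "upper_tail": self.upper_tail,
            "candidates": list(self.candidates),
            "epsilon": self.epsilon,
            "scale_pca": self.scale_pca,
            "seed": self.seed,
        }


@dataclass
class PipelineResult:
    """Everything a full run computes, before it is written to disk."""

    mesh: LabeledMesh
    fields: dict
    trimmed: dict[str, StressSample]
    trace: ConvergenceTrace
    profile: IntervalProfile
    pca: PcaSummary
    contrasts: pd.DataFrame

    @property
    def pc12_variance_pct(self) -> float:
        return float(self.pca.variance_pct[:2].sum())


def _contrast_table(
    fields: dict, scenarios: tuple[Scenario, ...], trim_fraction: float
) -> pd.DataFrame:
    rows = []
    for scenario in scenarios:
        het = fields[f"{scenario.label}_heterogeneous"]
        hom = fields[f"{scenario.label}_homogeneous"]
        for region in REGION_ORDER:
            med_het, med_hom, W, p = region_median_contrast(
                het, hom, region, trim_fraction
            )
            rows.append(
                {
                    "scenario": scenario.label,
                    "region": region,
                    "median_het_MPa": med_het,
                    "median_hom_MPa": med_hom,
                    "W": W,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, out_dir=None) -> PipelineResult:
    """Run the full analysis; optionally write the result bundle to disk.

    Stages: mesh (load or generate) -> 8 simulations -> per-simulation 2%
    trim -> interval-count convergence -> profile at the chosen count ->
    standardized PCA -> per-scenario region-wise treatment contrasts.
    """
    if config.mesh_file:
        mesh = read_mesh(config.mesh_file)
    else:
        mesh = generate_mandible_mesh(config.mandible)
    fields = run_biting_suite(mesh, config.materials, config.scenarios)
    trimmed = {
        label: trim_top_stress(sample_from_field(f), config.trim_fraction)
        for label, f in fields.items()
    }
    samples = list(trimmed.values())
    trace = convergence_select(
        samples,
        candidates=config.candidates,
        epsilon=config.epsilon,
        upper_tail=config.upper_tail,
        scale=config.scale_pca,
    )
    profile = build_profile(samples, trace.chosen, upper_tail=config.upper_tail)
    pca = pca_profiles(profile, scale=config.scale_pca)
    contrasts = _contrast_table(fields, config.scenarios, config.trim_fraction)
    result = PipelineResult(mesh, fields, trimmed, trace, profile, pca, contrasts)
    if out_dir is not None:
        write_bundle(result, config, out_dir)
    return result


# ---------------------------------------------------------------------------
# bundle output


def profile_frame(profile: IntervalProfile) -> pd.DataFrame:
    cols = [f"interval_{i + 1:02d}" for i in range(profile.n_intervals)]
    return pd.DataFrame(profile.proportions, index=profile.labels, columns=cols)


def write_bundle(result: PipelineResult, config: RunConfig, out_dir) -> Path:
    """Write CSV/VTK/JSON artifacts plus a manifest and markdown report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    profile_frame(result.profile).to_csv(out / "interval_profiles.csv", index_label="simulation")
    pd.DataFrame(
        {
            "component": np.arange(1, len(result.pca.variance_pct) + 1),
            "variance_pct": result.pca.variance_pct,
        }
    ).to_csv(out / "pca_variance.csv", index=False)
    pd.DataFrame(
        result.pca.scores,
        index=result.profile.labels,
        columns=[f"PC{i + 1}" for i in range(result.pca.scores.shape[1])],
    ).to_csv(out / "pca_scores.csv", index_label="simulation")
    result.contrasts.to_csv(out / "region_contrasts.csv", index=False)
    pd.DataFrame(
        {
            "pair": [
                f"{a}->{b}"
                for a, b in zip(result.trace.candidates, result.trace.candidates[1:])
            ],
            "r2_pc1": result.trace.r2_pc1,
            "r2_pc2": result.trace.r2_pc2,
        }
    ).to_csv(out / "convergence_trace.csv", index=False)
    for label, f in result.fields.items():
        df = pd.DataFrame(
            {
                "element_id": np.arange(f.n_elements),
                "region": f.region,
                "volume_um3": f.volume,
                "stress_xx": f.stress[:, 0],
                "stress_yy": f.stress[:, 1],
                "stress_zz": f.stress[:, 2],
                "stress_xy": f.stress[:, 3],
                "stress_yz": f.stress[:, 4],
                "stress_zx": f.stress[:, 5],
                "von_mises": f.sigma_vm,
            }
        )
        df.to_csv(out / f"elements_{label}.csv", index=False)
        mesh_out = result.mesh.copy()
        mesh_out.cell_fields = {
            "von_mises": f.sigma_vm,
            "von_mises_normalized": normalize_stress(f),
            "volume": f.volume,
        }
        write_mesh(mesh_out, out / f"field_{label}.vtk", format="vtk")
    manifest = {
        "package": "mandifem",
        "version": __version__,
        "python": platform.python_version(),
        "config": config.to_dict(),
        "mesh": {"nodes": result.mesh.n_nodes, "elements": result.mesh.n_elements},
        "chosen_intervals": result.trace.chosen,
        "pc1_pc2_variance_pct": result.pc12_variance_pct,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "report.md").write_text(_report_markdown(result))
    return out


def _report_markdown(result: PipelineResult) -> str:
    lines = [
        "# Biting-suite analysis report",
        "",
        f"- mesh: {result.mesh.n_nodes} nodes, {result.mesh.n_elements} TET10 elements",
        f"- simulations: {len(result.fields)}",
        f"- chosen interval count: {result.trace.chosen}",
        f"- PC1+PC2 variance explained: {result.pc12_variance_pct:.1f}%",
        "",
        "## Region-wise treatment contrasts (heterogeneous vs homogeneous)",
        "",
        result.contrasts.to_markdown(index=False),
        "",
    ]
    strike = result.contrasts[result.contrasts.scenario.str.startswith("strike")]
    mm_up = (
        strike[strike.region == "MM"].median_het_MPa
        >= strike[strike.region == "MM"].median_hom_MPa
    ).all()
    blade_down = (
        strike[strike.region == "BLADE"].median_het_MPa
        <= strike[strike.region == "BLADE"].median_hom_MPa
    ).all()
    lines.append(
        f"Strike scenarios: MM median stress higher under heterogeneous E: {mm_up}; "
        f"BLADE median stress lower under heterogeneous E: {blade_down}."
    )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# supplementary-table readers


def read_supplementary_table(
    path, kind: str, column_map: dict[str, str] | None = None
):
    """Read a tabular export of a supplementary data file.

    kind = "S1_sites": site table -> list of SiteRecord.
    kind = "S3_profiles": simulations x intervals proportions -> IntervalProfile
        (warns via ValueError if any row sum deviates from 1 by > 1e-6).
    kind = "S4_elements": per-element stress/volume rows with a ``simulation``
        column -> {label: StressSample}.
    """
    if kind == "S1_sites":
        return read_site_table(path, column_map)
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    if kind == "S3_profiles":
        label_col = df.columns[0]
        labels = df[label_col].astype(str).tolist()
        props = df.drop(columns=[label_col]).to_numpy(dtype=float)
        sums = props.sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-6)
        if bad.size:
            raise ValueError(
                f"profile rows {bad.tolist()} do not sum to 1 (sums {sums[bad]})"
            )
        return IntervalProfile(labels, props, np.array([]))
    if kind == "S4_elements":
        required = {"simulation", "von_mises", "volume_um3"}
        missing = required - set(df.columns)
        if missing:
            raise KeyError(
                f"S4 table lacks column(s) {sorted(missing)}; available: {list(df.columns)}"
            )
        out: dict[str, StressSample] = {}
        for label, grp in df.groupby("simulation", sort=False):
            region = grp["region"].to_numpy() if "region" in grp.columns else None
            out[str(label)] = StressSample(
                str(label),
                grp["von_mises"].to_numpy(dtype=float),
                grp["volume_um3"].to_numpy(dtype=float),
                region=region,
            )
        return out
    raise ValueError(f"unknown supplementary table kind '{kind}'")


def synth_bundle(
    mandible: MandibleParams, sites: SiteTableParams, out_dir
) -> Path:
    """Write a synthetic mesh + site table + manifest (the `synth` command)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mesh = generate_mandible_mesh(mandible)
    write_mesh(mesh, out / "mandible.vtk", format="vtk")
    write_mesh(mesh, out / "mandible.inp", format="abaqus_inp")
    records = generate_site_table(sites)
    write_site_table(records, out / "sites.csv")
    manifest = {
        "package": "mandifem",
        "version": __version__,
        "mandible": asdict(mandible),
        "n_sites": len(records),
        "mesh": {"nodes": mesh.n_nodes, "elements": mesh.n_elements},
        "seed": {"mandible": mandible.seed, "sites": sites.seed},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
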