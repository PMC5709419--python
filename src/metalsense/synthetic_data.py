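"""Seeded synthetic titration datasets.

Generates competition and anisotropy titrations with the exact forward
models of :mod:`metalsense.binding_fits` plus additive Gaussian noise
(relative to each point's noise-free signal, or absolute in signal units).
Every generator takes an explicit seed and is bit-reproducible for a fixed
seed; the generating truth is returned (and written) alongside the data so
parameter-recovery studies can score themselves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .binding_fits import (
    ANISOTROPY_DESIGNS,
    CHELATOR_KD,
    COMPETITION_DESIGNS,
    CompetitionModel,
    DnaBindingModel,
    TitrationCurve,
    simulate_anisotropy,
    simulate_competition,
)
from .sensor_params import packaged_registry_path

__all__ = [
    "NoiseSpec",
    "generate_competition_dataset",
    "generate_anisotropy_dataset",
    "packaged_fixtures",
    "write_titration_csv",
]

DEFAULT_NOISE_LEVEL = 0.01  # 1% relative Gaussian


@dataclass(frozen=True)
class NoiseSpec:
    kind: str = "relative_gaussian"  # or "absolute_gaussian"
    level: float = DEFAULT_NOISE_LEVEL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("relative_gaussian", "absolute_gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.level < 0:
            raise ValueError("noise level must be >= 0")


def _apply_noise(signal: np.ndarray, noise: NoiseSpec) -> np.ndarray:
    if noise.level == 0.0:
        return signal.copy()
    rng = np.random.default_rng(noise.seed)
    if noise.kind == "relative_gaussian":
        return signal * (1.0 + noise.level * rng.standard_normal(signal.shape))
    return signal + noise.level * rng.standard_normal(signal.shape)


def generate_competition_dataset(
    design: CompetitionModel,
    truth_kd: float,
    n_points: int = 21,
    noise: NoiseSpec = NoiseSpec(),
) -> tuple[TitrationCurve, dict]:
    """Competition titration over a linear metal grid with Gaussian noise.

    The metal grid spans 0 to 1.2x the stoichiometric capacity
    (probe + protein sites) so the competitive region is fully covered.
    Returns the noisy curve and a truth record.
    """
    if n_points < 6:
        raise ValueError("n_points must be >= 6")
    if not (truth_kd > 0):
        raise ValueError("truth_kd must be > 0")
    capacity = design.probe_total + design.site_total
    metal_totals = np.linspace(0.0, 1.2 * capacity, n_points)
    clean = simulate_competition(design, truth_kd, metal_totals)
    noisy = TitrationCurve(
        metal_totals,
        _apply_noise(clean.signal, noise),
        titrant="metal",
        meta={"model": design, "noise": noise},
    )
    truth = {
        "kind": "competition",
        "probe": design.probe,
        "probe_kd_M": design.probe_kd,
        "truth_kd_M": truth_kd,
        "noise_kind": noise.kind,
        "noise_level": noise.level,
        "seed": noise.seed,
    }
    return noisy, truth


def generate_anisotropy_dataset(
    design: DnaBindingModel,
    truth_kd: float,
    n_points: int = 21,
    noise: NoiseSpec = NoiseSpec(),
) -> tuple[TitrationCurve, dict]:
    """Anisotropy titration over a log protein grid with Gaussian noise.

    Protein totals (monomer basis) are log-spaced from Kd/100 to 100x Kd
    around the assembly-corrected dissociation constant, covering both
    baseline and saturation.
    """
    if n_points < 6:
        raise ValueError("n_points must be >= 6")
    if not (truth_kd > 0):
        raise ValueError("truth_kd must be > 0")
    centre = truth_kd * design.assembly_size  # monomer basis
    protein_totals = np.geomspace(centre / 100.0, centre * 100.0, n_points)
    clean = simulate_anisotropy(design, truth_kd, protein_totals)
    noisy = TitrationCurve(
        protein_totals,
        _apply_noise(clean.signal, noise),
        titrant="protein",
        meta={"model": design, "noise": noise},
    )
    truth = {
        "kind": "anisotropy",
        "stoichiometry": design.stoichiometry,
        "truth_kd_M": truth_kd,
        "noise_kind": noise.kind,
        "noise_level": noise.level,
        "seed": noise.seed,
    }
    return noisy, truth


def write_titration_csv(curve: TitrationCurve, path: Path, header_note: str = "") -> None:
    """Write a titration as CSV with a leading comment line naming the model."""
    path = Path(path)
    with path.open("w") as fh:
        if header_note:
            fh.write(f"# {header_note}\n")
        curve.to_frame().to_csv(fh, index=False)


def packaged_fixtures(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the full fixture set: sensor registry, chelator constants, and
    one seeded example dataset (CSV + JSON truth sidecar) per experimental
    design.  Returns a name -> path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    registry_dst = outdir / "sensor_registry.json"
    registry_dst.write_text(packaged_registry_path().read_text())
    written["sensor_registry"] = registry_dst

    chel = outdir / "chelator_constants.json"
    chel.write_text(json.dumps({"kd_M": CHELATOR_KD}, indent=2) + "\n")
    written["chelator_constants"] = chel

    for i, (name, (design, truth_kd)) in enumerate(COMPETITION_DESIGNS.items()):
        curve, truth = generate_competition_dataset(
            design, truth_kd, noise=NoiseSpec(seed=seed + i)
        )
        csv_path = outdir / f"{name}.csv"
        write_titration_csv(
            curve, csv_path, f"competition titration, probe {design.probe}, seed {seed + i}"
        )
        (outdir / f"{name}.truth.json").write_text(json.dumps(truth, indent=2) + "\n")
        written[name] = csv_path

    for j, (name, (design, truth_kd)) in enumerate(ANISOTROPY_DESIGNS.items()):
        curve, truth = generate_anisotropy_dataset(
            design, truth_kd, noise=NoiseSpec(seed=seed + 100 + j)
        )
        csv_path = outdir / f"{name}.csv"
        write_titration_csv(
            curve, csv_path, f"anisotropy titration, {design.stoichiometry}, seed {seed + 100 + j}"
        )
        (outdir / f"{name}.truth.json").write_text(json.dumps(truth, indent=2) + "\n")
        written[name] = csv_path

    return written
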