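"""Readers and writers for the package's on-disk dialects.

Spectra, mu-spectra and depth profiles are plain CSV (comma, ".",
UTF-8, header row); phantom volumes are NIfTI pairs (activity float,
medium label) with a JSON sidecar naming the media; camera configuration
is TOML or JSON with one schema.  Every artifact writer can attach a
JSON sidecar with the config hash, seed and package version.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .forward import CameraModel, EnergySpectrum, Phantom
from .geometry import Collimator
from .laplace import DepthProfile, MuSpectrum
from .transport import CrystalSlab

__all__ = [
    "write_spectra_csv", "read_spectra_csv",
    "write_mu_spectrum_csv", "read_mu_spectrum_csv",
    "write_depth_profile_csv", "read_depth_profile_csv",
    "write_phantom", "read_phantom",
    "load_camera_config", "write_sidecar",
]


# ---------------------------------------------------------------------------
# spectra CSV: pixel_id, e_lo_keV, e_hi_keV, counts


def write_spectra_csv(spectrum: EnergySpectrum, path) -> None:
    npix, nbin = spectrum.values.shape
    df = pd.DataFrame({
        "pixel_id": np.repeat(np.arange(npix), nbin),
        "pixel_x_cm": np.repeat(spectrum.pixels[:, 0], nbin),
        "pixel_y_cm": np.repeat(spectrum.pixels[:, 1], nbin),
        "e_lo_keV": np.tile(spectrum.bin_edges[:-1], npix),
        "e_hi_keV": np.tile(spectrum.bin_edges[1:], npix),
        "counts": spectrum.values.ravel(),
    })
    df.to_csv(path, index=False)


def read_spectra_csv(path, kind: str = "counts") -> EnergySpectrum:
    df = pd.read_csv(path)
    pixel_ids = df["pixel_id"].unique()
    first = df[df["pixel_id"] == pixel_ids[0]]
    edges = np.append(first["e_lo_keV"].to_numpy(),
                      first["e_hi_keV"].to_numpy()[-1])
    pixels, values = [], []
    for pid in pixel_ids:
        block = df[df["pixel_id"] == pid]
        pixels.append((block["pixel_x_cm"].iloc[0],
                       block["pixel_y_cm"].iloc[0]))
        values.append(block["counts"].to_numpy())
    return EnergySpectrum(pixels=np.array(pixels), bin_edges=edges,
                          values=np.array(values), kind=kind)


def write_mu_spectrum_csv(spec: MuSpectrum, path) -> None:
    pd.DataFrame({"mu_per_cm": spec.mu, "value": spec.values}).to_csv(
        path, index=False)


def read_mu_spectrum_csv(path) -> MuSpectrum:
    df = pd.read_csv(path)
    return MuSpectrum(mu=df["mu_per_cm"].to_numpy(),
                      values=df["value"].to_numpy())


def write_depth_profile_csv(profile: DepthProfile, path) -> None:
    pd.DataFrame({"depth_cm": profile.depths,
                  "abar": profile.values}).to_csv(path, index=False)


def read_depth_profile_csv(path) -> DepthProfile:
    df = pd.read_csv(path)
    return DepthProfile(depths=df["depth_cm"].to_numpy(),
                        values=df["abar"].to_numpy())


# ---------------------------------------------------------------------------
# phantom NIfTI


def _phantom_paths(prefix) -> tuple[Path, Path, Path]:
    prefix = Path(prefix)
    stem = prefix.name
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[:-len(suffix)]
    base = prefix.parent / stem
    return (base.with_name(base.name + "_activity.nii.gz"),
            base.with_name(base.name + "_medium.nii.gz"),
            base.with_name(base.name + "_phantom.json"))


def write_phantom(phantom: Phantom, prefix) -> list[Path]:
    """Write activity + medium NIfTI volumes and a JSON descriptor."""
    act_p, med_p, meta_p = _phantom_paths(prefix)
    affine = np.diag(list(phantom.voxel_size) + [1.0])
    affine[:3, 3] = phantom.origin
    nib.save(nib.Nifti1Image(phantom.activity.astype(np.float32), affine),
             act_p)
    nib.save(nib.Nifti1Image(phantom.medium.astype(np.int16), affine), med_p)
    with open(meta_p, "w") as fh:
        json.dump({"medium_names": list(phantom.medium_names),
                   "voxel_size_cm": list(phantom.voxel_size),
                   "origin_cm": list(phantom.origin),
                   "meta": phantom.meta}, fh, indent=2)
    return [act_p, med_p, meta_p]


def read_phantom(prefix) -> Phantom:
    act_p, med_p, meta_p = _phantom_paths(prefix)
    with open(meta_p) as fh:
        meta = json.load(fh)
    act = np.asarray(nib.load(act_p).dataobj, dtype=float)
    med = np.asarray(nib.load(med_p).dataobj, dtype=np.int16)
    return Phantom(activity=act, medium=med,
                   medium_names=tuple(meta["medium_names"]),
                   voxel_size=tuple(meta["voxel_size_cm"]),
                   origin=tuple(meta["origin_cm"]),
                   meta=meta.get("meta", {}))


# ---------------------------------------------------------------------------
# camera config


def load_camera_config(path) -> CameraModel:
    """Camera/collimator config from TOML or JSON (same schema).

    Keys: kind ("parallel"|"pinhole"), focal_length_cm, aperture_mm,
    hole_mm, hole_length_mm, septa_mm, wall_cm (w, h, t), window_kev
    (lo, hi), pixel_pitch_cm, extent_cm (w, h), resolution_r,
    reference_kev, crystal {material, thickness_mm}.
    """
    path = Path(path)
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            cfg = tomllib.load(fh)
    else:
        with open(path) as fh:
            cfg = json.load(fh)
    kind = cfg.get("kind", "pinhole")
    mm = 0.1  # mm -> cm
    coll = Collimator(
        kind=kind,
        focal_length=cfg.get("focal_length_cm"),
        aperture_diameter=(cfg["aperture_mm"] * mm
                           if "aperture_mm" in cfg else None),
        hole_diameter=cfg["hole_mm"] * mm if "hole_mm" in cfg else None,
        hole_length=(cfg["hole_length_mm"] * mm
                     if "hole_length_mm" in cfg else None),
        septal_thickness=cfg["septa_mm"] * mm if "septa_mm" in cfg else None,
        front_wall=tuple(cfg["wall_cm"]) if "wall_cm" in cfg else None,
    )
    crystal = None
    if "crystal" in cfg:
        crystal = CrystalSlab(material=cfg["crystal"]["material"],
                              thickness=cfg["crystal"]["thickness_mm"] * mm)
    return CameraModel(
        collimator=coll,
        crystal=crystal,
        resolution_r=cfg.get("resolution_r", 0.0),
        reference_energy=cfg.get("reference_kev", 511.0),
        window=tuple(cfg.get("window_kev", (50.0, 350.0))),
        pixel_pitch=cfg.get("pixel_pitch_cm", 0.5),
        extent=tuple(cfg.get("extent_cm", (45.0, 25.0))),
    )


# ---------------------------------------------------------------------------
# provenance sidecar


def write_sidecar(artifact_path, config: dict, seed: int | None = None) -> Path:
    """JSON sidecar (<artifact>.meta.json) with config hash, seed, version."""
    blob = json.dumps(config, sort_keys=True, default=str)
    side = Path(str(artifact_path) + ".meta.json")
    with open(side, "w") as fh:
        json.dump({"config_hash": hashlib.sha256(blob.encode()).hexdigest(),
                   "seed": seed, "package_version": __version__,
                   "config": config}, fh, indent=2)
    return side
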