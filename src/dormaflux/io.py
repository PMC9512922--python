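"""File formats: session TIFFs with JSON manifests, calibrated images,
caliper/metabolite/expression CSVs, GMT gene sets.

Raw sessions are stored as a multi-page 16-bit TIFF (one page per frame
role) with a JSON sidecar naming the roles; calibrated images as 32-bit
float TIFF with a JSON provenance sidecar.  Generator ground truth is
written to separate files that no analysis stage reads.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .correction import CalibratedImage, ImagingSession
from .survival import VolumeTrajectory
from .synthetic import MetaboliteTable, SessionTruth

__all__ = [
    "write_session",
    "read_session",
    "write_calibrated",
    "read_calibrated",
    "cohort_to_csv",
    "cohort_from_csv",
    "metabolite_table_to_csv",
    "metabolite_table_from_csv",
    "read_gmt",
]

FRAME_ROLES = (
    "probe_frame",
    "dark_frame",
    "background_frame",
    "phantom_frame",
    "rhodamine_frame",
)


def write_session(
    session: ImagingSession,
    outdir: str | Path,
    truth: SessionTruth | None = None,
    *,
    extra_manifest: dict | None = None,
) -> Path:
    """Write one session as multi-page uint16 TIFF + JSON manifest.

    Frames are rounded and clipped to the 16-bit range.  The latent truth,
    if given, goes to a separate float TIFF + JSON never read by the
    correction stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pages = np.stack(
        [
            np.clip(np.round(getattr(session, role)), 0, 65535).astype(np.uint16)
            for role in FRAME_ROLES
        ]
    )
    tifffile.imwrite(outdir / "session.tif", pages)
    manifest = {
        "frame_roles": list(FRAME_ROLES),
        "probe": session.probe,
        "mouse_id": session.mouse_id,
        "timepoint": session.timepoint,
        "session_date": session.session_date,
        "exposure_s": session.exposure_s,
    }
    manifest.update(extra_manifest or {})
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if truth is not None:
        tifffile.imwrite(
            outdir / "truth.tif",
            np.stack(
                [
                    truth.true_signal_field.astype(np.float32),
                    truth.beam_profile.astype(np.float32),
                ]
            ),
        )
        (outdir / "truth.json").write_text(
            json.dumps(
                {
                    "day_gain": truth.day_gain,
                    "dark_offset": truth.dark_offset,
                    "autofluorescence": truth.autofluorescence,
                },
                indent=2,
            )
        )
    return outdir


def read_session(indir: str | Path) -> ImagingSession:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    pages = tifffile.imread(indir / "session.tif")
    frames = {role: pages[i] for i, role in enumerate(manifest["frame_roles"])}
    return ImagingSession(
        probe=manifest.get("probe", "NBDG"),
        mouse_id=manifest.get("mouse_id", ""),
        timepoint=manifest.get("timepoint", ""),
        session_date=manifest.get("session_date", ""),
        exposure_s=manifest.get("exposure_s"),
        **frames,
    )


def write_calibrated(image: CalibratedImage, outdir: str | Path, stem: str) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(outdir / f"{stem}.tif", image.pixels.astype(np.float32))
    tifffile.imwrite(
        outdir / f"{stem}_mask.tif", image.valid_mask.astype(np.uint8)
    )
    (outdir / f"{stem}.json").write_text(
        json.dumps(
            {
                "probe": image.probe,
                "mouse_id": image.mouse_id,
                "timepoint": image.timepoint,
                "qc_flags": image.qc_flags,
            },
            indent=2,
        )
    )
    return outdir / f"{stem}.tif"


def read_calibrated(path: str | Path) -> CalibratedImage:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    pixels = tifffile.imread(path)
    mask_path = path.with_name(path.stem + "_mask.tif")
    mask = tifffile.imread(mask_path).astype(bool) if mask_path.exists() else None
    return CalibratedImage(
        pixels=pixels,
        probe=meta["probe"],
        mouse_id=meta["mouse_id"],
        timepoint=meta["timepoint"],
        valid_mask=mask,
        qc_flags=meta.get("qc_flags", {}),
    )


def cohort_to_csv(trajectories: list[VolumeTrajectory], path: str | Path) -> None:
    """Caliper CSV: mouse_id, arm, day, length_mm, width_mm."""
    frame = pd.concat([t.to_frame() for t in trajectories], ignore_index=True)
    frame.drop(columns=["volume_mm3"]).to_csv(path, index=False)


def cohort_from_csv(path: str | Path) -> list[VolumeTrajectory]:
    frame = pd.read_csv(path)
    out = []
    for (mouse, arm), sub in frame.groupby(["mouse_id", "arm"], sort=True):
        sub = sub.sort_values("day")
        out.append(
            VolumeTrajectory(
                mouse_id=str(mouse),
                arm=str(arm),
                days=sub["day"].to_numpy(),
                lengths=sub["length_mm"].to_numpy(),
                widths=sub["width_mm"].to_numpy(),
            )
        )
    return out


def metabolite_table_to_csv(table: MetaboliteTable, path: str | Path) -> None:
    """CSV with metabolites as columns; a class header row precedes samples."""
    path = Path(path)
    mets = list(table.abundances.columns)
    lines = ["sample,group," + ",".join(mets)]
    lines.append(
        "#class,," + ",".join(str(table.metabolite_class[m]) for m in mets)
    )
    for sample in table.abundances.index:
        vals = ",".join(
            "" if pd.isna(v) else repr(float(v))
            for v in table.abundances.loc[sample]
        )
        lines.append(f"{sample},{table.group[sample]},{vals}")
    path.write_text("\n".join(lines) + "\n")


def metabolite_table_from_csv(path: str | Path) -> MetaboliteTable:
    lines = Path(path).read_text().strip().splitlines()
    header = lines[0].split(",")
    mets = header[2:]
    class_row = lines[1].split(",")
    classes = pd.Series(dict(zip(mets, class_row[2:])))
    samples, groups, rows = [], [], []
    for line in lines[2:]:
        cells = line.split(",")
        samples.append(cells[0])
        groups.append(cells[1])
        rows.append([float(c) if c else np.nan for c in cells[2:]])
    return MetaboliteTable(
        abundances=pd.DataFrame(rows, index=samples, columns=mets),
        metabolite_class=classes,
        group=pd.Series(groups, index=samples),
        provenance=[f"read from {Path(path).name}"],
    )


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file: one gene set per line, tab-separated
    (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().strip().splitlines():
        parts = line.rstrip().split("\t")
        if len(parts) < 3:
            continue
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
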