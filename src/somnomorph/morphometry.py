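"""Parse FreeSurfer aseg/aparc stats files into a canonical morphometry table.

The table holds 174 morphometric variables per subject: 38 subcortical
volumes (aseg.stats), plus volume and average thickness of the 34
Desikan-Killiany cortical parcels in each hemisphere (2 x 34 = 68 volumes
and 68 thicknesses from lh/rh aparc.stats).  Intracranial volume (ICV) is
read from the ``EstimatedTotalIntraCranialVol`` measure line of aseg.stats.

aseg.stats can list more segmentations than are analysed; the 38 retained
structures are pinned below (FreeSurfer 5.1-era labels) and can be
overridden.  Units are taken as written in the files (mm^3, mm).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "ASEG_STRUCTURES",
    "DESIKAN_PARCELS",
    "MORPH_COLUMNS",
    "COVARIATE_COLUMNS",
    "parse_aseg",
    "parse_aparc",
    "assemble",
]

_LATERAL = (
    "Lateral-Ventricle",
    "Inf-Lat-Vent",
    "Cerebellum-White-Matter",
    "Cerebellum-Cortex",
    "Thalamus-Proper",
    "Caudate",
    "Putamen",
    "Pallidum",
    "Hippocampus",
    "Amygdala",
    "Accumbens-area",
    "VentralDC",
    "choroid-plexus",
)

_MIDLINE = (
    "3rd-Ventricle",
    "4th-Ventricle",
    "Brain-Stem",
    "CSF",
    "Optic-Chiasm",
    "WM-hypointensities",
    "non-WM-hypointensities",
    "CC_Posterior",
    "CC_Mid_Posterior",
    "CC_Central",
    "CC_Mid_Anterior",
    "CC_Anterior",
)

#: The 38 retained subcortical segmentations.
ASEG_STRUCTURES: tuple[str, ...] = (
    tuple(f"Left-{s}" for s in _LATERAL)
    + tuple(f"Right-{s}" for s in _LATERAL)
    + _MIDLINE
)

#: The 34 Desikan-Killiany cortical parcels (per hemisphere).
DESIKAN_PARCELS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)

HEMISPHERES: tuple[str, ...] = ("lh", "rh")

#: Canonical column order of the 174 morphometric variables.
MORPH_COLUMNS: tuple[str, ...] = (
    ASEG_STRUCTURES
    + tuple(f"{h}_{p}_volume" for h in HEMISPHERES for p in DESIKAN_PARCELS)
    + tuple(f"{h}_{p}_thickness" for h in HEMISPHERES for p in DESIKAN_PARCELS)
)
assert len(MORPH_COLUMNS) == 174

COVARIATE_COLUMNS: tuple[str, ...] = ("icv", "age", "sex")

_ICV_MEASURE = "EstimatedTotalIntraCranialVol"


def _data_rows(path: Path) -> tuple[list[list[str]], list[str] | None, float | None]:
    """Split a FreeSurfer stats file into data rows, column headers and ICV."""
    col_headers: list[str] | None = None
    icv: float | None = None
    rows: list[list[str]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("ColHeaders"):
                col_headers = body.split()[1:]
            elif body.startswith("Measure") and _ICV_MEASURE in body:
                parts = [p.strip() for p in body.split(",")]
                icv = float(parts[-2])
            continue
        rows.append(line.split())
    return rows, col_headers, icv


def parse_aseg(
    path, structures: Sequence[str] = ASEG_STRUCTURES
) -> tuple[dict[str, float], float]:
    """Parse an aseg.stats file.

    Returns
    -------
    volumes : dict
        ``StructName -> Volume_mm3`` for the retained structures (others are
        parsed but dropped).  A missing retained structure triggers a warning
        listing the absent names.
    icv : float
        Estimated total intracranial volume in mm^3.

    Raises
    ------
    ValueError
        On a missing ICV measure line, a duplicate StructName, or a file with
        no data rows.
    """
    rows, headers, icv = _data_rows(Path(path))
    if not rows:
        raise ValueError(f"{path}: no data rows (comment-only or empty stats file)")
    if icv is None:
        raise ValueError(f"{path}: missing '# Measure {_ICV_MEASURE}' line")
    if headers:
        i_name = headers.index("StructName")
        i_vol = headers.index("Volume_mm3")
    else:  # FreeSurfer default column layout
        i_name, i_vol = 4, 3
    all_volumes: dict[str, float] = {}
    for row in rows:
        name = row[i_name]
        if name in all_volumes:
            raise ValueError(f"{path}: duplicate StructName {name!r}")
        all_volumes[name] = float(row[i_vol])
    missing = [s for s in structures if s not in all_volumes]
    if missing:
        warnings.warn(
            f"{path}: {len(structures) - len(missing)} of {len(structures)} retained "
            f"structures found; missing: {missing}",
            stacklevel=2,
        )
    return {s: all_volumes[s] for s in structures if s in all_volumes}, icv


def parse_aparc(path, hemisphere: str) -> dict[str, tuple[float, float]]:
    """Parse an aparc.stats file into ``parcel -> (GrayVol, ThickAvg)``.

    Parcel names not in the Desikan-Killiany list are retained verbatim with
    a warning.  Raises on an empty file or an unknown hemisphere.
    """
    if hemisphere not in HEMISPHERES:
        raise ValueError(f"hemisphere must be one of {HEMISPHERES}, got {hemisphere!r}")
    rows, headers, _ = _data_rows(Path(path))
    if not rows:
        raise ValueError(f"{path}: no data rows (comment-only or empty stats file)")
    if headers:
        i_name = headers.index("StructName")
        i_vol = headers.index("GrayVol")
        i_thick = headers.index("ThickAvg")
    else:
        i_name, i_vol, i_thick = 0, 3, 4
    out: dict[str, tuple[float, float]] = {}
    for row in rows:
        name = row[i_name]
        if name not in DESIKAN_PARCELS:
            warnings.warn(f"{path}: unknown parcel {name!r} retained verbatim", stacklevel=2)
        if name in out:
            raise ValueError(f"{path}: duplicate parcel {name!r}")
        out[name] = (float(row[i_vol]), float(row[i_thick]))
    return out


def assemble(
    subjects: Mapping[str, Path],
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the subjects x 174 morphometry table (+ icv, age, sex).

    Parameters
    ----------
    subjects : mapping of subject id -> directory
        Each directory must contain ``aseg.stats``, ``lh.aparc.stats`` and
        ``rh.aparc.stats``.  A subject with a missing or unparsable file is
        excluded with a warning; the column set is unaffected.
    covariates : DataFrame indexed by subject id with ``age`` and ``sex``,
        merged into the result next to the file-derived ``icv``.
    """
    records: list[dict[str, float]] = []
    index: list[str] = []
    for subject, directory in subjects.items():
        directory = Path(directory)
        try:
            volumes, icv = parse_aseg(directory / "aseg.stats")
            row: dict[str, float] = dict(volumes)
            for hemi in HEMISPHERES:
                parcels = parse_aparc(directory / f"{hemi}.aparc.stats", hemi)
                for parcel, (vol, thick) in parcels.items():
                    row[f"{hemi}_{parcel}_volume"] = vol
                    row[f"{hemi}_{parcel}_thickness"] = thick
            row["icv"] = icv
        except (OSError, ValueError) as exc:
            warnings.warn(f"subject {subject!r} excluded: {exc}", stacklevel=2)
            continue
        records.append(row)
        index.append(subject)
    table = pd.DataFrame(records, index=pd.Index(index, name="subject"))
    table = table.reindex(columns=list(MORPH_COLUMNS) + ["icv"])
    if covariates is not None:
        table = table.join(covariates[["age", "sex"]], how="left")
    return table
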