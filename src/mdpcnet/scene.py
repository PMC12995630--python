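"""Hyperspectral scene container and file I/O.

The in-memory unit is :class:`HsiScene`: a reflectance cube ``(rows, cols,
bands)`` plus an integer label map where ``0`` marks unannotated pixels and
``1..C`` are class ids. Readers normalize every on-disk interleave (BSQ / BIL /
BIP) to band-axis-last.

Supported formats:

* dense-array archive (``.npz``) — the canonical lossless round-trip format;
* ENVI header + raw binary pair (labels in a sibling ``<stem>_gt`` pair);
* (Geo)TIFF via :mod:`tifffile` (no CRS handling, bands as samples);
* MAT containers (classic via :func:`scipy.io.loadmat`, HDF5-backed via h5py),
  read-only;
* paletted PNG export for label maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "HsiScene",
    "SceneSummary",
    "SceneFormatError",
    "SceneValidationError",
    "load_scene",
    "save_scene",
    "scene_summary",
    "save_label_png",
    "load_label_png",
]


class SceneFormatError(ValueError):
    """File could not be parsed under the detected or declared dialect."""


class SceneValidationError(ValueError):
    """Scene contents violate the container invariants."""


_DEFAULT_PALETTE = np.array([
    (230, 25, 75), (60, 180, 75), (255, 225, 25), (0, 130, 200),
    (245, 130, 48), (145, 30, 180), (70, 240, 240), (240, 50, 230),
    (210, 245, 60), (250, 190, 212), (0, 128, 128), (220, 190, 255),
    (170, 110, 40), (255, 250, 200), (128, 0, 0), (170, 255, 195),
    (128, 128, 0), (255, 215, 180), (0, 0, 128), (128, 128, 128),
], dtype=np.uint8)


def default_colors(n: int) -> list[tuple[int, int, int]]:
    reps = -(-n // len(_DEFAULT_PALETTE))
    pal = np.tile(_DEFAULT_PALETTE, (reps, 1))[:n]
    return [tuple(int(v) for v in row) for row in pal]


@dataclass
class HsiScene:
    """A reflectance cube with its pixel-level class annotation."""

    cube: np.ndarray
    labels: np.ndarray
    class_names: list[str]
    class_colors: list[tuple[int, int, int]] = field(default_factory=list)
    wavelengths_nm: list[float] | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.cube = np.asarray(self.cube, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.cube.ndim != 3:
            raise SceneValidationError(f"cube must be rows x cols x bands, got {self.cube.shape}")
        if self.labels.shape != self.cube.shape[:2]:
            raise SceneValidationError(
                f"labels shape {self.labels.shape} does not match cube spatial shape "
                f"{self.cube.shape[:2]}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.all(self.labels == np.round(self.labels)):
                raise SceneValidationError("labels must be integers")
            self.labels = self.labels.astype(np.int64)
        else:
            self.labels = self.labels.astype(np.int64)
        bad = ~np.isfinite(self.cube)
        if bad.any():
            r, c, b = np.argwhere(bad)[0]
            raise SceneValidationError(
                f"cube contains non-finite value at pixel (row={r}, col={c}, band={b})")
        c_max = len(self.class_names)
        offenders = np.setdiff1d(np.unique(self.labels), np.arange(c_max + 1))
        if offenders.size:
            raise SceneValidationError(
                f"label values outside 0..{c_max}: {offenders.tolist()}")
        if not self.class_colors:
            self.class_colors = default_colors(c_max)
        if len(self.class_colors) != c_max:
            raise SceneValidationError("class_colors length must equal number of classes")
        if self.wavelengths_nm is not None:
            wl = np.asarray(self.wavelengths_nm, dtype=float)
            if wl.size != self.cube.shape[2]:
                raise SceneValidationError("wavelengths_nm length must equal band count")
            if np.any(np.diff(wl) <= 0):
                raise SceneValidationError("wavelengths_nm must be strictly increasing")
            self.wavelengths_nm = wl.tolist()

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.cube.shape  # type: ignore[return-value]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def labeled_coords(self, class_id: int | None = None) -> np.ndarray:
        """(row, col) coordinates of labeled pixels, optionally of one class."""
        mask = self.labels > 0 if class_id is None else self.labels == class_id
        return np.argwhere(mask)


@dataclass(frozen=True)
class SceneSummary:
    per_class_pixel_counts: list[int]
    n_unlabeled: int
    shape: tuple[int, int, int]


def scene_summary(scene: HsiScene) -> SceneSummary:
    """Exact labeled-pixel inventory per class id ``1..C``."""
    counts = np.bincount(scene.labels.ravel(), minlength=scene.n_classes + 1)
    return SceneSummary(
        per_class_pixel_counts=[int(v) for v in counts[1:scene.n_classes + 1]],
        n_unlabeled=int(counts[0]),
        shape=scene.shape,
    )


# ---------------------------------------------------------------------------
# archive (npz) — canonical round-trip format

def _save_archive(scene: HsiScene, path: Path) -> Path:
    path = path.with_suffix(".npz") if path.suffix != ".npz" else path
    np.savez(
        path,
        cube=scene.cube,
        labels=scene.labels,
        class_names=np.array(scene.class_names, dtype=object),
        class_colors=np.asarray(scene.class_colors, dtype=np.int64),
        wavelengths_nm=np.asarray(
            scene.wavelengths_nm if scene.wavelengths_nm is not None else [],
            dtype=np.float64),
        provenance=np.array(scene.provenance),
    )
    return path


def _load_archive(path: Path) -> HsiScene:
    import zipfile

    try:
        with np.load(path, allow_pickle=True) as z:
            wl = z["wavelengths_nm"]
            return HsiScene(
                cube=z["cube"],
                labels=z["labels"],
                class_names=[str(s) for s in z["class_names"]],
                class_colors=[tuple(int(v) for v in row) for row in z["class_colors"]],
                wavelengths_nm=wl.tolist() if wl.size else None,
                provenance=str(z["provenance"]),
            )
    except (KeyError, zipfile.BadZipFile) as exc:
        raise SceneFormatError(f"{path} is not a scene archive: {exc}") from exc


# ---------------------------------------------------------------------------
# ENVI header + raw pair

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
                5: np.float64, 12: np.uint16, 13: np.uint32, 14: np.int64}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def _parse_envi_header(hdr_path: Path) -> dict:
    text = hdr_path.read_text()
    if not text.lstrip().upper().startswith("ENVI"):
        raise SceneFormatError(f"{hdr_path}: missing ENVI magic line")
    fields: dict[str, str] = {}
    body = text.split("\n", 1)[1] if "\n" in text else ""
    # brace-delimited values may span lines; normalize first
    import re

    body = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), body)
    for line in body.splitlines():
        if "=" not in line:
            continue
        key, val = line.split("=", 1)
        fields[key.strip().lower()] = val.strip()
    return fields


def _save_envi(scene: HsiScene, path: Path, interleave: str = "bsq") -> Path:
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise SceneFormatError(f"unknown ENVI interleave {interleave!r}")
    stem = path.with_suffix("")
    for arr, tag in ((scene.cube.astype(np.float32), ""),
                     (scene.labels.astype(np.int32)[:, :, None], "_gt")):
        rows, cols, bands = arr.shape
        if interleave == "bsq":
            raw = np.transpose(arr, (2, 0, 1))
        elif interleave == "bil":
            raw = np.transpose(arr, (0, 2, 1))
        else:
            raw = arr
        base = Path(str(stem) + tag)
        base.with_suffix(".img").write_bytes(np.ascontiguousarray(raw).tobytes())
        lines = [
            "ENVI",
            f"samples = {cols}",
            f"lines = {rows}",
            f"bands = {bands}",
            "header offset = 0",
            "file type = ENVI Standard",
            f"data type = {_ENVI_CODES[raw.dtype]}",
            f"interleave = {interleave}",
            "byte order = 0",
        ]
        if tag == "" and scene.wavelengths_nm is not None:
            wl = ", ".join(f"{v:g}" for v in scene.wavelengths_nm)
            lines.append(f"wavelength = {{{wl}}}")
        if tag == "_gt":
            names = ", ".join(scene.class_names)
            lines.append(f"class names = {{{names}}}")
        base.with_suffix(".hdr").write_text("\n".join(lines) + "\n")
    return stem.with_suffix(".hdr")


def _read_envi_array(hdr_path: Path) -> tuple[np.ndarray, dict]:
    fields = _parse_envi_header(hdr_path)
    try:
        rows = int(fields["lines"])
        cols = int(fields["samples"])
        bands = int(fields["bands"])
        dtype = np.dtype(_ENVI_DTYPES[int(fields["data type"])])
        interleave = fields.get("interleave", "bsq").lower()
    except (KeyError, ValueError) as exc:
        raise SceneFormatError(f"{hdr_path}: malformed ENVI header ({exc})") from exc
    if int(fields.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")
    img = hdr_path.with_suffix(".img")
    if not img.exists():
        raw_candidates = [p for p in (hdr_path.with_suffix(".raw"), hdr_path.with_suffix(".dat")) if p.exists()]
        if not raw_candidates:
            raise SceneFormatError(f"no raw data file next to {hdr_path}")
        img = raw_candidates[0]
    data = np.frombuffer(img.read_bytes(), dtype=dtype)
    if data.size != rows * cols * bands:
        raise SceneFormatError(
            f"{img}: expected {rows * cols * bands} samples, found {data.size}")
    if interleave == "bsq":
        arr = data.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        arr = data.reshape(rows, bands, cols).transpose(0, 2, 1)
    elif interleave == "bip":
        arr = data.reshape(rows, cols, bands)
    else:
        raise SceneFormatError(f"{hdr_path}: unknown interleave {interleave!r}")
    return np.ascontiguousarray(arr), fields


def _parse_brace_list(raw: str) -> list[str]:
    return [s.strip() for s in raw.strip().strip("{}").split(",") if s.strip()]


def _load_envi(path: Path) -> HsiScene:
    hdr = path if path.suffix == ".hdr" else path.with_suffix(".hdr")
    cube, fields = _read_envi_array(hdr)
    gt_hdr = Path(str(hdr.with_suffix("")) + "_gt.hdr")
    if not gt_hdr.exists():
        raise SceneFormatError(f"label pair {gt_hdr} not found")
    labels, gt_fields = _read_envi_array(gt_hdr)
    labels = labels[:, :, 0]
    names = _parse_brace_list(gt_fields.get("class names", ""))
    if not names:
        names = [f"class_{i}" for i in range(1, int(labels.max(initial=0)) + 1)]
    wl_raw = fields.get("wavelength")
    wl = [float(v) for v in _parse_brace_list(wl_raw)] if wl_raw else None
    return HsiScene(cube=cube, labels=labels, class_names=names,
                    wavelengths_nm=wl, provenance=f"envi:{hdr.name}")


# ---------------------------------------------------------------------------
# (Geo)TIFF via tifffile

def _save_geotiff(scene: HsiScene, path: Path) -> Path:
    import tifffile

    path = path.with_suffix(".tif") if path.suffix not in (".tif", ".tiff") else path
    tifffile.imwrite(path, scene.cube.astype(np.float32), photometric="minisblack",
                     planarconfig="contig",
                     metadata={"class_names": scene.class_names})
    gt = Path(str(path.with_suffix("")) + "_gt.tif")
    tifffile.imwrite(gt, scene.labels.astype(np.int32))
    return path


def _load_geotiff(path: Path) -> HsiScene:
    import tifffile

    try:
        cube = np.asarray(tifffile.imread(path), dtype=np.float64)
    except Exception as exc:  # noqa: BLE001 - normalized to dialect error
        raise SceneFormatError(f"{path}: unreadable TIFF ({exc})") from exc
    if cube.ndim == 2:
        cube = cube[:, :, None]
    elif cube.ndim == 3 and cube.shape[0] < min(cube.shape[1:]):
        cube = np.moveaxis(cube, 0, -1)  # planar band-first layout
    gt = Path(str(path.with_suffix("")) + "_gt.tif")
    if not gt.exists():
        raise SceneFormatError(f"label pair {gt} not found")
    labels = np.asarray(tifffile.imread(gt))
    names = None
    with tifffile.TiffFile(path) as tf:
        meta = tf.shaped_metadata
        if meta and "class_names" in meta[0]:
            names = [str(s) for s in meta[0]["class_names"]]
    if names is None:
        names = [f"class_{i}" for i in range(1, int(labels.max(initial=0)) + 1)]
    return HsiScene(cube=cube, labels=labels, class_names=names,
                    provenance=f"geotiff:{path.name}")


# ---------------------------------------------------------------------------
# MAT containers (read-only)

def _load_mat(path: Path, cube_var: str | None = None,
              labels_var: str | None = None) -> HsiScene:
    arrays: dict[str, np.ndarray] = {}
    try:
        from scipy.io import loadmat

        raw = loadmat(path)
        arrays = {k: np.asarray(v) for k, v in raw.items() if not k.startswith("__")}
    except (NotImplementedError, ValueError) as primary:
        # v7.3-era containers are HDF5-backed; scipy refuses them
        import h5py

        try:
            with h5py.File(path, "r") as f:
                def visit(name: str, obj) -> None:
                    if hasattr(obj, "shape") and obj.ndim in (2, 3):
                        arrays[name] = np.asarray(obj).T  # MATLAB column-major
                f.visititems(lambda n, o: visit(n, o))
        except OSError as exc:
            raise SceneFormatError(
                f"{path}: unreadable MAT container ({primary})") from exc
    except Exception as exc:  # noqa: BLE001
        raise SceneFormatError(f"{path}: unreadable MAT container ({exc})") from exc
    if not arrays:
        raise SceneFormatError(f"{path}: no array variables found")

    def pick(pred, explicit):
        if explicit is not None:
            if explicit not in arrays:
                raise SceneFormatError(f"{path}: variable {explicit!r} not present")
            return arrays[explicit]
        for name in sorted(arrays):
            if pred(arrays[name]):
                return arrays[name]
        return None

    cube = pick(lambda a: a.ndim == 3 and np.issubdtype(a.dtype, np.number), cube_var)
    labels = pick(lambda a: a.ndim == 2 and np.issubdtype(a.dtype, np.integer),
                  labels_var)
    if labels is None:  # fall back to any 2-D numeric with integral values
        labels = pick(lambda a: a.ndim == 2 and np.issubdtype(a.dtype, np.number)
                      and np.all(a == np.round(a)), None)
    if cube is None or labels is None:
        raise SceneFormatError(f"{path}: could not locate cube and label variables")
    names = [f"class_{i}" for i in range(1, int(labels.max(initial=0)) + 1)]
    return HsiScene(cube=cube, labels=labels, class_names=names,
                    provenance=f"mat:{path.name}")


# ---------------------------------------------------------------------------
# paletted PNG label maps

def save_label_png(labels: np.ndarray, class_colors: list[tuple[int, int, int]],
                   path: Path | str) -> Path:
    """Write an integer label map as a paletted PNG (0 = black background)."""
    from PIL import Image

    path = Path(path)
    labels = np.asarray(labels)
    if int(labels.max(initial=0)) > len(class_colors):
        raise SceneValidationError("missing color for some label value")
    img = Image.fromarray(labels.astype(np.uint8), mode="P")
    palette = [0, 0, 0]
    for rgb in class_colors:
        palette.extend(int(v) for v in rgb)
    palette.extend([0] * (768 - len(palette)))
    img.putpalette(palette)
    img.save(path)
    return path


def load_label_png(path: Path | str) -> np.ndarray:
    from PIL import Image

    with Image.open(path) as img:
        return np.asarray(img, dtype=np.int64)


# ---------------------------------------------------------------------------
# dispatch

def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".npz":
        return "archive"
    if suffix in (".hdr", ".img", ".raw"):
        return "envi"
    if suffix in (".tif", ".tiff"):
        return "geotiff"
    if suffix == ".mat":
        return "mat"
    raise SceneFormatError(f"cannot infer format of {path} (suffix {suffix!r})")


def load_scene(path: Path | str, format_hint: str = "auto", *,
               cube_var: str | None = None, labels_var: str | None = None) -> HsiScene:
    """Load and validate a scene; the band axis is always last in memory."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path) if format_hint == "auto" else format_hint
    if fmt == "archive":
        return _load_archive(path)
    if fmt == "envi":
        return _load_envi(path)
    if fmt == "geotiff":
        return _load_geotiff(path)
    if fmt == "mat":
        return _load_mat(path, cube_var, labels_var)
    raise SceneFormatError(f"unknown format {fmt!r}")


def save_scene(scene: HsiScene, path: Path | str, format: str = "archive",
               interleave: str = "bsq") -> Path:
    """Write a scene; the archive format round-trips bit-exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "archive":
        return _save_archive(scene, path)
    if format == "envi":
        return _save_envi(scene, path, interleave=interleave)
    if format == "geotiff":
        return _save_geotiff(scene, path)
    raise SceneFormatError(f"unknown format {format!r}")


def summary_json(scene: HsiScene) -> str:
    s = scene_summary(scene)
    return json.dumps({
        "shape": list(s.shape),
        "per_class_pixel_counts": s.per_class_pixel_counts,
        "n_unlabeled": s.n_unlabeled,
        "class_names": scene.class_names,
    }, indent=2)
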