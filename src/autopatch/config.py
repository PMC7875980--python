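"""XML run configuration.

A single XML file carries the protocol parameters and the stored pipette
calibration so a run can be adapted between setups without code changes.
"""

from __future__ import annotations

import dataclasses
import xml.etree.ElementTree as ET

import numpy as np

from .controller import PatchConfig
from .errors import ConfigurationError
from .pipette import CalibrationTransform

_TUPLE_FIELDS = {"alconox_position_um", "acsf_position_um"}


def save_config(path, patch_config: PatchConfig, calibration: CalibrationTransform | None = None) -> None:
    root = ET.Element("autopatch")
    pc = ET.SubElement(root, "patch")
    for f in dataclasses.fields(patch_config):
        value = getattr(patch_config, f.name)
        if value is None:
            continue
        el = ET.SubElement(pc, f.name)
        if f.name in _TUPLE_FIELDS:
            el.text = " ".join(repr(float(v)) for v in value)
        else:
            el.text = repr(value) if not isinstance(value, bool) else str(value)
    if calibration is not None:
        cal = ET.SubElement(root, "calibration")
        ET.SubElement(cal, "matrix").text = " ".join(repr(float(v)) for v in calibration.matrix.ravel())
        ET.SubElement(cal, "reference_tip_um").text = " ".join(
            repr(float(v)) for v in calibration.reference_tip_um
        )
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)


def load_config(path):
    """Load ``(PatchConfig, CalibrationTransform | None)`` from XML."""
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if root.tag != "autopatch":
        raise ConfigurationError(f"{path}: not an autopatch configuration file")
    kwargs = {}
    pc = root.find("patch")
    field_types = {f.name: f for f in dataclasses.fields(PatchConfig)}
    if pc is not None:
        for el in pc:
            if el.tag not in field_types:
                raise ConfigurationError(f"unknown patch parameter <{el.tag}>")
            text = (el.text or "").strip()
            if el.tag in _TUPLE_FIELDS:
                kwargs[el.tag] = tuple(float(v) for v in text.split())
            elif el.tag in ("spiral_points_per_turn", "baseline_window", "track_every_steps"):
                kwargs[el.tag] = int(text)
            else:
                kwargs[el.tag] = float(text)
    config = PatchConfig(**kwargs)
    calibration = None
    cal = root.find("calibration")
    if cal is not None:
        matrix = np.array([float(v) for v in cal.findtext("matrix", "").split()]).reshape(3, 3)
        ref_text = cal.findtext("reference_tip_um", "0 0 0")
        ref = np.array([float(v) for v in ref_text.split()])
        calibration = CalibrationTransform(matrix, ref)
    return config, calibration
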