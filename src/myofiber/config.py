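"""Parameter-file handling: declaration, generation, parsing, validation.

Every tunable carries a *pattern* (type and admissible range), a default
value, a documentation string and a verbosity class, and is validated on
parse, so a typo in a name or an out-of-range value fails before any solve.
Parameters live in named subsections; the parameters of the selected
geometry are read from the subsection named after the ``Geometry type``
value.  Any parameter missing from a file silently takes its default.

Two interchangeable formats are supported: a human-readable ``prm`` dialect
(``subsection``/``set name = value``/``end``) and ``json`` (nested objects,
string values).  A file generated in either format parses back to the same
configuration.
"""

from __future__ import annotations

import json as _json
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

MESH_SECTION = "Mesh and space discretization"
OUTPUT_SECTION = "Output"
SOLVER_SECTION = "Linear solver"
GEOMETRY_SECTIONS = ("Slab", "Left ventricle", "Left ventricle complete", "Left atrium")

VERBOSITY_LEVELS = ("minimal", "standard", "full")


# ------------------------------------------------------------------ patterns


class Pattern:
    def parse(self, text: str):  # pragma: no cover - abstract
        raise NotImplementedError

    def format(self, value) -> str:  # pragma: no cover - abstract
        raise NotImplementedError

    def describe(self) -> str:  # pragma: no cover - abstract
        raise NotImplementedError


class Selection(Pattern):
    def __init__(self, *options):
        self.options = options

    def parse(self, text):
        t = text.strip()
        if t not in self.options:
            raise ConfigurationError(f"value {t!r} not in {{{'|'.join(self.options)}}}")
        return t

    def format(self, value):
        return str(value)

    def describe(self):
        return "Selection " + "|".join(self.options)


class Bool(Pattern):
    def parse(self, text):
        t = text.strip().lower()
        if t in ("true", "yes", "1"):
            return True
        if t in ("false", "no", "0"):
            return False
        raise ConfigurationError(f"value {text!r} is not a boolean")

    def format(self, value):
        return "true" if value else "false"

    def describe(self):
        return "Bool"


class Double(Pattern):
    def __init__(self, lo=-np.inf, hi=np.inf, exclusive_lo=False):
        self.lo, self.hi, self.exclusive_lo = lo, hi, exclusive_lo

    def parse(self, text):
        try:
            v = float(text)
        except ValueError:
            raise ConfigurationError(f"value {text!r} is not a real number") from None
        if v < self.lo or v > self.hi or (self.exclusive_lo and v == self.lo):
            raise ConfigurationError(f"value {v} outside {self.describe()}")
        return v

    def format(self, value):
        return repr(float(value))

    def describe(self):
        left = "(" if self.exclusive_lo else "["
        return f"Double {left}{self.lo}, {self.hi}]"


class Integer(Pattern):
    def __init__(self, lo=0, hi=2**31):
        self.lo, self.hi = lo, hi

    def parse(self, text):
        try:
            v = int(text)
        except ValueError:
            raise ConfigurationError(f"value {text!r} is not an integer") from None
        if not self.lo <= v <= self.hi:
            raise ConfigurationError(f"value {v} outside [{self.lo}, {self.hi}]")
        return v

    def format(self, value):
        return str(int(value))

    def describe(self):
        return f"Integer [{self.lo}, {self.hi}]"


class String(Pattern):
    def parse(self, text):
        return text.strip()

    def format(self, value):
        return str(value)

    def describe(self):
        return "Anything"


class IntList(Pattern):
    def parse(self, text):
        parts = [p for p in text.replace(",", " ").split() if p]
        try:
            return tuple(int(p) for p in parts)
        except ValueError:
            raise ConfigurationError(f"value {text!r} is not a list of integers") from None

    def format(self, value):
        return ", ".join(str(int(v)) for v in value)

    def describe(self):
        return "List of Integer"


class Point3(Pattern):
    def parse(self, text):
        parts = [p for p in text.replace(",", " ").split() if p]
        if len(parts) != 3:
            raise ConfigurationError(f"value {text!r} is not a 3D point 'x, y, z'")
        try:
            return tuple(float(p) for p in parts)
        except ValueError:
            raise ConfigurationError(f"value {text!r} is not a 3D point") from None

    def format(self, value):
        return ", ".join(repr(float(v)) for v in value)

    def describe(self):
        return "Point: x, y, z"


# -------------------------------------------------------------- declaration


@dataclass
class Param:
    section: str
    name: str
    pattern: Pattern
    default: object
    doc: str
    verbosity: str = "minimal"  # lowest verbosity at which the param is printed


def _angle_params(section):
    return [
        Param(section, "alpha endo", Double(-180, 180), -60.0,
              "Helical angle on the endocardium [deg]."),
        Param(section, "alpha epi", Double(-180, 180), 60.0,
              "Helical angle on the epicardium [deg]."),
        Param(section, "beta endo", Double(-180, 180), 0.0,
              "Sheetlet angle on the endocardium [deg]."),
        Param(section, "beta epi", Double(-180, 180), 0.0,
              "Sheetlet angle on the epicardium [deg]."),
    ]


def _declare() -> list[Param]:
    p: list[Param] = []
    p += [
        Param(MESH_SECTION, "Geometry type",
              Selection(*GEOMETRY_SECTIONS), "Slab",
              "Kind of geometry in input; the matching subsection is parsed."),
        Param(MESH_SECTION, "Element type", Selection("Tet", "Hex"), "Hex",
              "Volumetric element type of the input mesh."),
        Param(MESH_SECTION, "FE space degree", Integer(1, 3), 1,
              "Degree of the continuous FE space for the Laplace problems."),
        Param(MESH_SECTION, "Scaling factor", Double(0, np.inf, exclusive_lo=True), 1.0,
              "Coordinate scaling applied on read (1e-3: mesh in millimeters)."),
        Param(MESH_SECTION, "Filename", String(), "mesh.msh",
              "Path of the input labeled mesh (.msh, ASCII v2.2/v4.1)."),
    ]
    # --- Slab
    p += [
        Param("Slab", "Sphere slab", Bool(), False,
              "true: spherical slab with pole-point base/apex; false: ventricular slab."),
        Param("Slab", "Sphere with radial fibers", Bool(), False,
              "Spherical slab only: exchange fiber and sheet directions."),
        Param("Slab", "Tags endo", IntList(), (20,), "Endocardial surface labels."),
        Param("Slab", "Tags epi", IntList(), (10,), "Epicardial surface labels."),
        Param("Slab", "Tags base up", IntList(), (40,), "Top (base) surface labels."),
        Param("Slab", "Tags base down", IntList(), (50,), "Bottom (apex) surface labels."),
        Param("Slab", "North pole", Point3(), (0.0, 0.0, 0.03),
              "Epicardial north-pole coordinates [m] (spherical slab)."),
        Param("Slab", "South pole", Point3(), (0.0, 0.0, -0.03),
              "Epicardial south-pole coordinates [m] (spherical slab)."),
    ] + _angle_params("Slab")
    # --- Based left ventricle
    p += [
        Param("Left ventricle", "Algorithm type", Selection("RL", "BT"), "BT",
              "Normal-direction rule: constant basal normal (RL) or apex-to-base potential (BT)."),
        Param("Left ventricle", "Tags endo", IntList(), (20,), "Endocardial surface labels."),
        Param("Left ventricle", "Tags epi", IntList(), (10,), "Epicardial surface labels."),
        Param("Left ventricle", "Tags base", IntList(), (30,), "Basal-plane surface labels."),
        Param("Left ventricle", "Normal to base", Point3(), (0.0, 0.0, 1.0),
              "Outward normal to the basal plane (RL)."),
        Param("Left ventricle", "Apex", Point3(), (0.0, 0.0, -0.06),
              "Apex epicardial coordinates [m] (BT)."),
    ] + _angle_params("Left ventricle")
    # --- Complete left ventricle
    p += [
        Param("Left ventricle complete", "Tags endo", IntList(), (20,), "Endocardial surface labels."),
        Param("Left ventricle complete", "Tags epi", IntList(), (10,), "Epicardial surface labels."),
        Param("Left ventricle complete", "Tags MV", IntList(), (70,), "Mitral valve ring labels."),
        Param("Left ventricle complete", "Tags AV", IntList(), (75,), "Aortic valve ring labels."),
        Param("Left ventricle complete", "Apex", Point3(), (0.0, 0.0, -0.06),
              "Apex epicardial coordinates [m]."),
    ] + _angle_params("Left ventricle complete") + [
        Param("Left ventricle complete", "alpha endo OT", Double(-180, 180), -60.0,
              "Helical angle on the endocardium in the outflow-tract region [deg]."),
        Param("Left ventricle complete", "alpha epi OT", Double(-180, 180), 60.0,
              "Helical angle on the epicardium in the outflow-tract region [deg]."),
        Param("Left ventricle complete", "beta endo OT", Double(-180, 180), 0.0,
              "Sheetlet angle on the endocardium in the outflow-tract region [deg]."),
        Param("Left ventricle complete", "beta epi OT", Double(-180, 180), 0.0,
              "Sheetlet angle on the epicardium in the outflow-tract region [deg]."),
    ]
    # --- Left atrium
    p += [
        Param("Left atrium", "Appendage", Bool(), False,
              "true: realistic atrium with an appendage apex point."),
        Param("Left atrium", "Tags endo", IntList(), (20,), "Endocardial surface labels."),
        Param("Left atrium", "Tags epi", IntList(), (10,), "Epicardial surface labels."),
        Param("Left atrium", "Tags MV", IntList(), (70,), "Mitral valve ring labels."),
        Param("Left atrium", "Tags LPV", IntList(), (80,), "Left pulmonary vein ring labels."),
        Param("Left atrium", "Tags RPV", IntList(), (90,), "Right pulmonary vein ring labels."),
        Param("Left atrium", "Apex", Point3(), (0.0, 0.0, 0.0),
              "Appendage apex coordinates [m] (Appendage = true)."),
        Param("Left atrium", "Tau bundle MV", Double(0, 1), 0.65,
              "Mitral-valve bundle size threshold in [0, 1]."),
        Param("Left atrium", "Tau bundle LPV", Double(0, 1), 0.65,
              "Left-pulmonary-vein bundle size threshold in [0, 1]."),
        Param("Left atrium", "Tau bundle RPV", Double(0, 1), 0.10,
              "Right-pulmonary-vein bundle size threshold in [0, 1]."),
    ]
    # --- Output / solver
    p += [
        Param(OUTPUT_SECTION, "Enable output", Bool(), True,
              "Write the fiber fields to disk after generation.", "standard"),
        Param(OUTPUT_SECTION, "Filename", String(), "fibers",
              "Output basename (XDMF+HDF5 or VTU).", "standard"),
        Param(SOLVER_SECTION, "Tolerance", Double(0, 1, exclusive_lo=True), 1e-12,
              "Relative tolerance of the conjugate-gradient solver.", "full"),
        Param(SOLVER_SECTION, "Max iterations", Integer(1, 10**9), 10_000,
              "Iteration cap of the conjugate-gradient solver.", "full"),
    ]
    return p


SCHEMA: list[Param] = _declare()
_BY_KEY = {(q.section, q.name): q for q in SCHEMA}


# -------------------------------------------------------------------- config


class LDRBMConfig:
    """Validated, fully-defaulted parameter set for one fiber generation."""

    def __init__(self, values=None):
        self.values = {k: p.default for k, p in _BY_KEY.items()}
        if values:
            for k, v in values.items():
                if k not in _BY_KEY:
                    raise ConfigurationError(f"unknown parameter {k[1]!r} in subsection {k[0]!r}")
                self.values[k] = v

    # dict-like access by (section, name)
    def __getitem__(self, key):
        return self.values[key]

    def set(self, section, name, value):
        if (section, name) not in _BY_KEY:
            raise ConfigurationError(f"unknown parameter {name!r} in subsection {section!r}")
        self.values[(section, name)] = value
        return self

    def geo(self, name):
        """Value of a parameter in the active geometry subsection."""
        key = (self.geometry_type, name)
        if key not in _BY_KEY:
            raise ConfigurationError(
                f"parameter {name!r} not declared for geometry {self.geometry_type!r}"
            )
        return self.values[key]

    # convenience accessors
    @property
    def geometry_type(self):
        return self.values[(MESH_SECTION, "Geometry type")]

    @property
    def element_type(self):
        return self.values[(MESH_SECTION, "Element type")]

    @property
    def fe_degree(self):
        return self.values[(MESH_SECTION, "FE space degree")]

    @property
    def scaling_factor(self):
        return self.values[(MESH_SECTION, "Scaling factor")]

    @property
    def mesh_filename(self):
        return self.values[(MESH_SECTION, "Filename")]

    @property
    def enable_output(self):
        return self.values[(OUTPUT_SECTION, "Enable output")]

    @property
    def output_filename(self):
        return self.values[(OUTPUT_SECTION, "Filename")]

    @property
    def solver_tolerance(self):
        return self.values[(SOLVER_SECTION, "Tolerance")]

    @property
    def solver_max_iterations(self):
        return self.values[(SOLVER_SECTION, "Max iterations")]

    def __eq__(self, other):
        return isinstance(other, LDRBMConfig) and self.values == other.values

    # ------------------------------------------------------------------ I/O
    @classmethod
    def defaults(cls, geometry: str | None = None) -> "LDRBMConfig":
        cfg = cls()
        if geometry is not None:
            cfg.set(MESH_SECTION, "Geometry type", Selection(*GEOMETRY_SECTIONS).parse(geometry))
        return cfg

    @classmethod
    def from_file(cls, path) -> "LDRBMConfig":
        path = str(path)
        if path.endswith(".json"):
            with open(path) as fh:
                tree = _json.load(fh)
        elif path.endswith(".prm"):
            with open(path) as fh:
                tree = _parse_prm(fh.read())
        elif path.endswith(".xml"):
            raise ConfigurationError(
                "xml parameter files are not supported; use .prm or .json"
            )
        else:
            raise ConfigurationError(f"unknown parameter-file extension: {path}")
        values = {}
        for section, body in tree.items():
            if not isinstance(body, dict):
                raise ConfigurationError(f"top-level entry {section!r} is not a subsection")
            for name, raw in body.items():
                key = (section, name)
                if key not in _BY_KEY:
                    raise ConfigurationError(
                        f"unknown parameter {name!r} in subsection {section!r}"
                    )
                try:
                    values[key] = _BY_KEY[key].pattern.parse(str(raw))
                except ConfigurationError as exc:
                    raise ConfigurationError(
                        f"parameter {name!r} in subsection {section!r}: {exc}"
                    ) from None
        return cls(values)

    def to_tree(self, verbosity: str = "standard") -> dict:
        if verbosity not in VERBOSITY_LEVELS:
            raise ConfigurationError(f"unknown verbosity {verbosity!r}")
        level = VERBOSITY_LEVELS.index(verbosity)
        tree: dict[str, dict[str, str]] = {}
        for p in SCHEMA:
            if VERBOSITY_LEVELS.index(p.verbosity) > level:
                continue
            tree.setdefault(p.section, {})[p.name] = p.pattern.format(
                self.values[(p.section, p.name)]
            )
        return tree

    def to_file(self, path, verbosity: str = "standard") -> None:
        path = str(path)
        tree = self.to_tree(verbosity)
        if path.endswith(".json"):
            with open(path, "w") as fh:
                _json.dump(tree, fh, indent=2)
                fh.write("\n")
        elif path.endswith(".prm"):
            with open(path, "w") as fh:
                fh.write(self._format_prm(tree))
        else:
            raise ConfigurationError(f"unknown parameter-file extension: {path}")

    def _format_prm(self, tree) -> str:
        out = []
        for section, body in tree.items():
            out.append(f"subsection {section}")
            for name, value in body.items():
                p = _BY_KEY[(section, name)]
                out.append(f"  # {p.doc}")
                out.append(f"  # Pattern: {p.pattern.describe()}")
                out.append(f"  set {name} = {value}")
            out.append("end")
            out.append("")
        return "\n".join(out)


def _parse_prm(text: str) -> dict:
    tree: dict[str, dict[str, str]] = {}
    stack: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("subsection "):
            stack.append(line[len("subsection "):].strip())
            if len(stack) > 1:
                raise ConfigurationError(f"line {lineno}: nested subsections are not supported")
        elif line == "end":
            if not stack:
                raise ConfigurationError(f"line {lineno}: 'end' without matching subsection")
            stack.pop()
        elif line.startswith("set "):
            if not stack:
                raise ConfigurationError(f"line {lineno}: 'set' outside any subsection")
            if "=" not in line:
                raise ConfigurationError(f"line {lineno}: malformed 'set' (missing '=')")
            name, value = line[len("set "):].split("=", 1)
            tree.setdefault(stack[-1], {})[name.strip()] = value.strip()
        else:
            raise ConfigurationError(f"line {lineno}: unrecognized statement {line!r}")
    if stack:
        raise ConfigurationError(f"unterminated subsection {stack[-1]!r}")
    return tree


def generate_params(path, verbosity: str = "standard", fmt: str | None = None) -> None:
    """Write a parameter file with every default, pattern and doc string."""
    path = str(path)
    if fmt is not None and not path.endswith("." + fmt):
        path = path + "." + fmt
    LDRBMConfig.defaults().to_file(path, verbosity=verbosity)
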