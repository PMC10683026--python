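"""Export of pull / adaptive-bias parameter fragments in .mdp dialect.

The toolkit never runs molecular dynamics; it emits the parameter
fragment the MD engine needs to steer along the cluster pull coordinates
or to run the accelerated-weight-histogram (AWH) bias on the two refined
CVs. Fragments are plain ``key = value`` lines in GROMACS .mdp style and
round-trip byte-identically through :func:`parse_md_config` /
:func:`render_md_config`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .contacts import PullCoordinateSet

#: Fine-tuned per-condition AWH force constants (kJ mol^-1 nm^-2) and
#: diffusion constants (nm^2 ps^-1) for the two CVs.
AWH_CONDITION_DEFAULTS: dict[str, dict[str, float]] = {
    "apo":        {"k_cv1": 10000, "k_cv2": 10000, "d_cv1": 0.001,  "d_cv2": 0.001},
    "adrenaline": {"k_cv1": 10000, "k_cv2": 10000, "d_cv1": 0.0005, "d_cv2": 0.0005},
    "alprenolol": {"k_cv1": 10000, "k_cv2": 10000, "d_cv1": 0.001,  "d_cv2": 0.001},
    "BI-167107":  {"k_cv1": 10000, "k_cv2": 10000, "d_cv1": 0.005,  "d_cv2": 0.005},
    "carazolol":  {"k_cv1": 10000, "k_cv2": 10000, "d_cv1": 0.001,  "d_cv2": 0.001},
    "formoterol": {"k_cv1": 10000, "k_cv2": 10000, "d_cv1": 0.001,  "d_cv2": 0.001},
    "mirabegron": {"k_cv1": 10000, "k_cv2": 10000, "d_cv1": 0.0005, "d_cv2": 0.0005},
    "salbutamol": {"k_cv1": 10000, "k_cv2": 10000, "d_cv1": 0.001,  "d_cv2": 0.001},
    "salmeterol": {"k_cv1": 10000, "k_cv2": 10000, "d_cv1": 0.001,  "d_cv2": 0.001},
    "timolol":    {"k_cv1": 10000, "k_cv2": 10000, "d_cv1": 0.001,  "d_cv2": 0.001},
}


@dataclass
class AwhParameters:
    """Adaptive-bias parameters on the two refined CVs.

    Defaults: 4 communicating walkers, a point counts as covered only
    once all points within the cover diameter are sampled, a growth
    factor of 2.0 that prolongs the initial stage before the final
    Wang-Landau refinement, and per-condition force/diffusion constants
    from :data:`AWH_CONDITION_DEFAULTS`.
    """

    condition: str = "apo"
    n_walkers: int = 4
    cover_diameter_nm: float = 0.4
    energy_cutoff_kj_mol: float = 120.0
    nst_sample: int = 10
    n_samples_update: int = 10
    growth_factor: float = 2.0
    cv1_range_nm: tuple[float, float] = (0.4, 1.3)
    cv2_range_nm: tuple[float, float] = (0.3, 1.0)
    force_constants: tuple[float, float] | None = None
    diffusion: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.force_constants is None or self.diffusion is None:
            row = AWH_CONDITION_DEFAULTS.get(self.condition)
            if row is None:
                raise ValueError(
                    f"unknown condition {self.condition!r}; pass force_constants "
                    f"and diffusion explicitly or use one of "
                    f"{sorted(AWH_CONDITION_DEFAULTS)}"
                )
            if self.force_constants is None:
                self.force_constants = (row["k_cv1"], row["k_cv2"])
            if self.diffusion is None:
                self.diffusion = (row["d_cv1"], row["d_cv2"])


def _fmt(value: float) -> str:
    """Format numbers without trailing noise (10000 not 10000.0)."""
    if float(value) == int(value):
        return str(int(value))
    return repr(float(value))


def _awh_pairs(params: AwhParameters) -> list[tuple[str, str]]:
    pairs = [
        ("awh", "yes"),
        ("awh-nbias", "1"),
        ("awh-share-multisim", "yes"),
        ("awh-nstsample", _fmt(params.nst_sample)),
        ("awh-nsamples-update", _fmt(params.n_samples_update)),
        ("awh1-error-init", "10"),
        ("awh1-growth", "exp-linear"),
        ("awh1-growth-factor", _fmt(params.growth_factor)),
        ("awh1-energy-cutoff", _fmt(params.energy_cutoff_kj_mol)),
        ("awh1-nwalkers", _fmt(params.n_walkers)),
        ("awh1-ndim", "2"),
    ]
    ranges = (params.cv1_range_nm, params.cv2_range_nm)
    for dim in (1, 2):
        lo, hi = ranges[dim - 1]
        pairs += [
            (f"awh1-dim{dim}-coord-provider", "pull"),
            (f"awh1-dim{dim}-coord-index", _fmt(dim)),
            (f"awh1-dim{dim}-start", _fmt(lo)),
            (f"awh1-dim{dim}-end", _fmt(hi)),
            (f"awh1-dim{dim}-force-constant", _fmt(params.force_constants[dim - 1])),
            (f"awh1-dim{dim}-diffusion", _fmt(params.diffusion[dim - 1])),
            (f"awh1-dim{dim}-cover-diameter", _fmt(params.cover_diameter_nm)),
        ]
    return pairs


def _pull_pairs(pull_set: PullCoordinateSet) -> list[tuple[str, str]]:
    pairs = [
        ("pull", "yes"),
        ("pull-ncoords", _fmt(len(pull_set))),
        ("pull-ngroups", _fmt(2 * sum(len(c.pairs) for c in pull_set.coordinates))),
    ]
    group = 1
    for k, coord in enumerate(pull_set.coordinates, start=1):
        pairs += [
            (f"pull-coord{k}-type", "umbrella"),
            (f"pull-coord{k}-geometry", "transformation"),
            (f"pull-coord{k}-k", _fmt(coord.force_constant_kj_mol_nm2)),
            (f"pull-coord{k}-init", _fmt(coord.target_nm)),
            (
                f"pull-coord{k}-expr",
                " + ".join(
                    f"{w:.6f}*d{group + 2 * m}_{group + 2 * m + 1}"
                    for m, w in enumerate(coord.weights)
                ),
            ),
            (
                f"pull-coord{k}-pairs",
                " ".join(f"{i}:{j}" for i, j in coord.pairs),
            ),
        ]
        group += 2 * len(coord.pairs)
    return pairs


def render_md_config(pairs: list[tuple[str, str]]) -> str:
    """Render ``key = value`` pairs as canonical .mdp text."""
    return "".join(f"{key} = {value}\n" for key, value in pairs)


def parse_md_config(text: str) -> list[tuple[str, str]]:
    """Parse .mdp-style text back into ordered (key, value) pairs.

    Comments (``;``) and blank lines are dropped; values keep their
    verbatim spelling so parse -> render round-trips canonical output
    byte-identically.
    """
    pairs = []
    for line in text.splitlines():
        line = line.split(";", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed .mdp line: {line!r}")
        key, value = line.split("=", 1)
        pairs.append((key.strip(), " ".join(value.split())))
    return pairs


def export_md_config(obj: PullCoordinateSet | AwhParameters, dialect: str = "gromacs") -> str:
    """Emit the MD-engine parameter fragment for a pull set or AWH setup."""
    if dialect != "gromacs":
        raise ValueError(f"unknown dialect {dialect!r}; only 'gromacs' is supported")
    if isinstance(obj, AwhParameters):
        return render_md_config(_awh_pairs(obj))
    if isinstance(obj, PullCoordinateSet):
        return render_md_config(_pull_pairs(obj))
    raise TypeError(f"cannot export {type(obj).__name__}")


def config_value(text: str, key: str) -> str:
    """Look up one key in an exported fragment."""
    for k, v in parse_md_config(text):
        if k == key:
            return v
    raise KeyError(key)
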