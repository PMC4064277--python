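"""Contiguity scoring functions, penalty schemes and named presets.

The aligner scores a run of ``n`` consecutive matching nucleotides with an
arbitrary non-decreasing function ``f(n)`` (with ``f(0) = 0``), applied
incrementally: extending a run from length ``n-1`` to ``n`` adds
``delta_f(n) = f(n) - f(n-1)``.  A linear ``f`` (constant increment)
recovers classic per-column match rewards; the shipped default is the cubic
``f(n) = n**3`` with penalties ``rho_m = 8`` (mismatch), ``rho_o = 200``
(gap open) and ``rho_e = 20`` (gap extension), which concentrate score on
short, highly contiguous motif matches: two consecutive matches already
equal one mismatch penalty, and three score above a single gap extension.

Four named presets cover the classic and generalized schemes:

========== ============== ===========
preset     f              gap model
========== ============== ===========
sw         linear (c=1)   linear
swga       linear (c=1)   affine
sw_plus    cubic          linear
swga_plus  cubic          affine
========== ============== ===========

The linear match reward ``c = 1`` used when degenerating to SW/SWGA is this
package's default, not a universal constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

__all__ = [
    "ContiguityFunction",
    "ScoringScheme",
    "ScoringError",
    "linear",
    "quadratic",
    "cubic",
    "exponential",
    "tabulated",
    "function_from_spec",
    "delta_f",
    "make_preset",
    "min_run_reaching",
    "PRESET_NAMES",
]


class ScoringError(ValueError):
    """Invalid scoring configuration or domain error."""


@dataclass(frozen=True)
class ContiguityFunction:
    """A cumulative score ``f(n)`` for a run of ``n`` contiguous matches.

    Invariants: ``f(0) == 0`` and ``f`` is non-decreasing on ``n >= 0``.
    ``is_linear`` is True iff ``f(n) = c * n`` for a constant ``c``, in
    which case the engine keeps a single contiguity-depth node per cell.
    """

    name: str
    evaluate: Callable[[int], float]
    is_linear: bool = False

    def __call__(self, n: int) -> float:
        return self.evaluate(n)

    def validate(self, upto: int = 16) -> None:
        if self.evaluate(0) != 0:
            raise ScoringError(f"contiguity function {self.name!r}: f(0) must be 0")
        prev = 0
        for n in range(1, upto + 1):
            cur = self.evaluate(n)
            if cur < prev:
                raise ScoringError(
                    f"contiguity function {self.name!r} decreases at n={n}"
                )
            prev = cur


def linear(c: float = 1) -> ContiguityFunction:
    """``f(n) = c * n`` — per-column match reward ``c`` (classic scoring)."""
    if c < 0:
        raise ScoringError("linear increment c must be non-negative")
    return ContiguityFunction(f"linear:{c:g}", lambda n: c * n, is_linear=True)


def quadratic() -> ContiguityFunction:
    """``f(n) = n**2``."""
    return ContiguityFunction("quadratic", lambda n: n * n)


def cubic() -> ContiguityFunction:
    """``f(n) = n**3`` — the default nonlinear contiguity reward."""
    return ContiguityFunction("cubic", lambda n: n**3)


def exponential(base: float = 2) -> ContiguityFunction:
    """``f(n) = base**n - 1`` (shifted so that f(0) = 0)."""
    if base <= 1:
        raise ScoringError("exponential base must exceed 1")
    return ContiguityFunction(f"exp:{base:g}", lambda n: base**n - 1)


def tabulated(values: Sequence[float], name: str = "tabulated") -> ContiguityFunction:
    """A contiguity function given as a table ``values[n] = f(n)``.

    ``values[0]`` must be 0 and the table must be non-decreasing.  Beyond
    the last entry the function extends with the table's final increment.
    """
    vals = list(values)
    if not vals or vals[0] != 0:
        raise ScoringError("tabulated values must start with f(0) = 0")
    for a, b in zip(vals, vals[1:]):
        if b < a:
            raise ScoringError("tabulated values must be non-decreasing")
    last_inc = vals[-1] - vals[-2] if len(vals) > 1 else 0
    top = len(vals) - 1

    def evaluate(n: int) -> float:
        if n <= top:
            return vals[n]
        return vals[top] + (n - top) * last_inc

    is_lin = len(vals) > 1 and all(
        vals[i + 1] - vals[i] == vals[1] for i in range(len(vals) - 1)
    )
    return ContiguityFunction(name, evaluate, is_linear=is_lin)


def function_from_spec(spec: str) -> ContiguityFunction:
    """Parse a function spec string: ``linear[:c]``, ``quadratic``, ``cubic``,
    ``exp[:base]`` or a comma-separated value table ``0,1,8,27``."""
    s = spec.strip().lower()
    if "," in s:
        try:
            vals = [float(x) for x in s.split(",")]
        except ValueError as exc:
            raise ScoringError(f"bad tabulated function spec {spec!r}") from exc
        ivals = [int(v) if float(v).is_integer() else v for v in vals]
        return tabulated(ivals)
    head, _, arg = s.partition(":")
    if head == "linear":
        c = float(arg) if arg else 1.0
        return linear(int(c) if c.is_integer() else c)
    if head == "quadratic":
        return quadratic()
    if head == "cubic":
        return cubic()
    if head in ("exp", "exponential"):
        b = float(arg) if arg else 2.0
        return exponential(int(b) if b.is_integer() else b)
    raise ScoringError(
        f"unknown contiguity function {spec!r}; expected linear[:c], "
        "quadratic, cubic, exp[:base] or a value table"
    )


def delta_f(fn: ContiguityFunction, n: int) -> float:
    """Incremental score ``f(n) - f(n-1)`` for extending a match run to ``n``.

    Raises :class:`ScoringError` for ``n < 1``.
    """
    if n < 1:
        raise ScoringError(f"delta_f requires n >= 1, got {n}")
    return fn.evaluate(n) - fn.evaluate(n - 1)


@dataclass(frozen=True)
class ScoringScheme:
    """Complete parameterization of the aligner.

    Parameters
    ----------
    fn:
        Contiguity function scoring runs of consecutive matches.
    mismatch_penalty:
        rho_m, subtracted per mismatch column (non-negative).
    gap_open:
        rho_o, extra cost of opening a gap (non-negative).  Ignored
        (treated as 0) when ``gap_model`` is ``"linear"``.
    gap_extend:
        rho_e, cost per gap column (non-negative).  A k-column affine gap
        costs ``rho_o + k * rho_e``.
    gap_model:
        ``"affine"`` or ``"linear"``.
    alignment_mode:
        ``"local"`` (score floor 0, maximal-scoring segment pair) or
        ``"global"`` (end-to-end, boundary gaps charged).
    band_width:
        Optional diagonal band half-width; ``None`` means unbanded.
    depth_cap:
        Optional cap C on contiguity depth: for ``n > C`` the increment is
        frozen at ``delta_f(C)`` and depth nodes beyond C are merged.
        ``None`` means unbounded (linear functions are always capped at 1
        internally, where the cap is exact).
    """

    fn: ContiguityFunction = field(default_factory=cubic)
    mismatch_penalty: float = 8
    gap_open: float = 200
    gap_extend: float = 20
    gap_model: str = "affine"
    alignment_mode: str = "local"
    band_width: Optional[int] = None
    depth_cap: Optional[int] = None

    def __post_init__(self) -> None:
        if self.gap_model not in ("affine", "linear"):
            raise ScoringError(f"unknown gap model {self.gap_model!r}")
        if self.alignment_mode not in ("local", "global"):
            raise ScoringError(f"unknown alignment mode {self.alignment_mode!r}")
        if self.mismatch_penalty < 0 or self.gap_open < 0 or self.gap_extend < 0:
            raise ScoringError("penalties must be non-negative")
        if self.band_width is not None and self.band_width < 1:
            raise ScoringError("band_width must be >= 1 when bounded")
        if self.depth_cap is not None and self.depth_cap < 1:
            raise ScoringError("depth_cap must be >= 1 when bounded")

    @property
    def effective_gap_open(self) -> float:
        """rho_o as charged (0 under the linear gap model)."""
        return 0 if self.gap_model == "linear" else self.gap_open

    @property
    def gap_open_cost(self) -> float:
        """Cost of the first column of a gap: rho_o_effective + rho_e."""
        return self.effective_gap_open + self.gap_extend

    @property
    def effective_depth_cap(self) -> Optional[int]:
        """The depth cap the engine applies (1 for linear f)."""
        if self.fn.is_linear:
            return 1
        return self.depth_cap

    def delta(self, n: int) -> float:
        """delta_f under this scheme's depth cap."""
        cap = self.effective_depth_cap
        if cap is not None and n > cap:
            n = cap
        return delta_f(self.fn, n)

    def run_score(self, length: int) -> float:
        """Cumulative score of a match run of ``length`` under the cap."""
        if length < 0:
            raise ScoringError("run length must be non-negative")
        cap = self.effective_depth_cap
        if cap is None or length <= cap:
            return self.fn.evaluate(length)
        return self.fn.evaluate(cap) + (length - cap) * delta_f(self.fn, cap)

    # -- flat key/value config serialization ------------------------------

    def to_config_text(self) -> str:
        lines = [
            f"function\t{self.fn.name}",
            f"mismatch\t{self.mismatch_penalty:g}",
            f"gap_open\t{self.gap_open:g}",
            f"gap_extend\t{self.gap_extend:g}",
            f"gap_model\t{self.gap_model}",
            f"mode\t{self.alignment_mode}",
            f"band\t{self.band_width if self.band_width is not None else 'none'}",
            f"depth_cap\t{self.depth_cap if self.depth_cap is not None else 'none'}",
        ]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config_text(cls, text: str) -> "ScoringScheme":
        kv = {}
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise ScoringError(f"config line {lineno}: expected 'key value'")
            kv[parts[0]] = parts[1].strip()

        def num(key, default):
            if key not in kv:
                return default
            v = float(kv[key])
            return int(v) if v.is_integer() else v

        def opt_int(key):
            v = kv.get(key, "none")
            return None if v.lower() == "none" else int(v)

        return cls(
            fn=function_from_spec(kv.get("function", "cubic")),
            mismatch_penalty=num("mismatch", 8),
            gap_open=num("gap_open", 200),
            gap_extend=num("gap_extend", 20),
            gap_model=kv.get("gap_model", "affine"),
            alignment_mode=kv.get("mode", "local"),
            band_width=opt_int("band"),
            depth_cap=opt_int("depth_cap"),
        )


_PRESET_ALIASES = {
    "sw+": "sw_plus",
    "swga+": "swga_plus",
    "sw_plus": "sw_plus",
    "swga_plus": "swga_plus",
    "sw": "sw",
    "swga": "swga",
}

PRESET_NAMES = ("sw", "swga", "sw_plus", "swga_plus")


def make_preset(name: str, **overrides) -> ScoringScheme:
    """Build a named scheme preset; keyword overrides replace fields.

    ``sw``: linear f (c=1), linear gaps.  ``swga``: linear f, affine gaps.
    ``sw_plus`` (alias ``sw+``): cubic f, linear gaps.  ``swga_plus``
    (alias ``swga+``): cubic f, affine gaps.  All default to local mode
    with penalties (8, 200, 20).
    """
    key = _PRESET_ALIASES.get(name.strip().lower())
    if key is None:
        raise ScoringError(
            f"unknown preset {name!r}; valid presets: sw, swga, sw+ (sw_plus), "
            "swga+ (swga_plus)"
        )
    base = {
        "sw": dict(fn=linear(1), gap_model="linear"),
        "swga": dict(fn=linear(1), gap_model="affine"),
        "sw_plus": dict(fn=cubic(), gap_model="linear"),
        "swga_plus": dict(fn=cubic(), gap_model="affine"),
    }[key]
    scheme = ScoringScheme(**base)
    if overrides:
        scheme = replace(scheme, **overrides)
    return scheme


def min_run_reaching(
    fn: ContiguityFunction, threshold: float, strict: bool = False, max_n: int = 1_000_000
) -> int:
    """Smallest run length n with ``f(n) >= threshold`` (or ``>`` if strict).

    Raises :class:`ScoringError` if the threshold is non-positive or cannot
    be reached (f plateaus below it).
    """
    if threshold <= 0:
        raise ScoringError("threshold must be positive")
    prev = 0.0
    plateau = 0
    for n in range(1, max_n + 1):
        val = fn.evaluate(n)
        if (val > threshold) if strict else (val >= threshold):
            return n
        plateau = plateau + 1 if val == prev else 0
        if plateau > 64:  # bounded f: increments vanished long before threshold
            break
        prev = val
    raise ScoringError(f"threshold {threshold} unreachable for {fn.name}")
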