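"""Registry of 67 published reflectance vegetation indices.

Each index is declared as an :class:`IndexDefinition`: the bands it needs
(plain reflectance ``R<nm>`` or first-derivative ``D<nm>``), a printable
formula string, and an evaluation function over resolved band values.
The registry holds 59 singleton indices plus 8 ratio-of-indices family
members (TCARI/OSAVIj, CARI/OSAVIj, MCARIi/OSAVIj for j in {1,2}).

Two indices are printed ambiguously in the source list and support both a
``canonical`` and a ``literal`` reading (see ``msr_mode`` / ``rep_mode``):

* MSR1/MSR2 — canonical uses a square root on the ``ratio + 1`` term;
  literal divides by ``ratio + 1`` directly.
* REP — canonical interpolates across the red edge with denominator
  ``R760 - R710``; literal honours the printed ``R760 + R710``.

SR12–SR14 carry a product in the denominator exactly as published here;
this is flagged in their notes rather than silently changed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import OutOfRangeError
from .features import UNDEFINED, FeatureTable
from .preprocess import DenoiseConfig, band_value, derivative_value, wavelet_denoise
from .spectra import SampleRecord, Spectrum, average_replicates

logger = logging.getLogger(__name__)

Bands = dict[str, float]


def _div(num: float, den: float) -> float:
    return num / den if den != 0.0 else UNDEFINED

def _sqrt(x: float) -> float:
    return math.sqrt(x) if x >= 0.0 else UNDEFINED

def _nd(a: float, b: float) -> float:
    """Sum-normalized difference (a - b) / (a + b)."""
    return _div(a - b, a + b)


@dataclass(frozen=True)
class IndexDefinition:
    """One vegetation index: required bands plus an arithmetic expression."""

    name: str
    family: str
    source_eq: str
    expression: str
    bands: tuple[tuple[float, bool], ...]  # (center nm, derivative flag)
    fn: Callable[[Bands], float]
    notes: str = ""

    def band_keys(self) -> list[str]:
        return [("D%g" if deriv else "R%g") % c for c, deriv in self.bands]


def _bands(*centers: float, deriv: tuple[float, ...] = ()) -> tuple:
    out = [(c, False) for c in centers]
    out += [(c, True) for c in deriv]
    return tuple(out)


# --- composite sub-expressions reused by the ratio families -----------------

def _cari(b: Bands) -> float:
    return (b["R700"] - b["R670"]) - 0.2 * (b["R700"] + b["R550"])

def _mcari1(b: Bands) -> float:
    return ((b["R700"] - b["R670"]) - 0.2 * (b["R700"] - b["R550"])) \
        * _div(b["R700"], b["R670"])

def _mcari2(b: Bands) -> float:
    return ((b["R750"] - b["R705"]) - 0.2 * (b["R750"] - b["R550"])) \
        * _div(b["R750"], b["R705"])

def _tcari(b: Bands) -> float:
    return 3.0 * ((b["R700"] - b["R670"])
                  - 0.2 * (b["R700"] - b["R550"]) * _div(b["R700"], b["R670"]))

def _osavi1(b: Bands) -> float:
    return 1.16 * _div(b["R800"] - b["R670"], b["R700"] + b["R670"] + 0.16)

def _osavi2(b: Bands) -> float:
    return 1.16 * _div(b["R750"] - b["R705"], b["R750"] + b["R705"] + 0.16)


def builtin_index_catalog(msr_mode: str = "canonical",
                          rep_mode: str = "canonical") -> list[IndexDefinition]:
    """The built-in registry of all 67 vegetation indices.

    Parameters
    ----------
    msr_mode, rep_mode
        ``"canonical"`` (default) or ``"literal"`` reading of the MSR and
        REP formulas; see the module docstring.
    """
    if msr_mode not in ("canonical", "literal"):
        raise ValueError(f"invalid msr_mode {msr_mode!r}")
    if rep_mode not in ("canonical", "literal"):
        raise ValueError(f"invalid rep_mode {rep_mode!r}")

    defs: list[IndexDefinition] = []

    def add(name, family, eq, expr, bands, fn, notes=""):
        defs.append(IndexDefinition(name, family, eq, expr, bands, fn, notes))

    ND = "normalized_difference"
    SRF = "simple_ratio"

    # normalized difference vegetation indices (eqs 1-8)
    for name, eq, hi, lo in [
        ("NDVI1", "1", 800, 670), ("NDVI2", "2", 780, 670),
        ("NDVI3", "3", 573, 440), ("NDVI4", "4", 410, 365),
        ("NDVI5", "5", 503, 483), ("NDVI6", "6", 800, 680),
        ("NDVI7", "7", 1220, 710), ("NDVI8", "8", 801, 550),
    ]:
        add(name, ND, eq, f"(R{hi}-R{lo})/(R{hi}+R{lo})", _bands(hi, lo),
            lambda b, hi=hi, lo=lo: _nd(b[f"R{hi}"], b[f"R{lo}"]))

    # normalized difference indices (eqs 9-16)
    for name, eq, hi, lo in [
        ("NDI1", "9", 790, 720), ("NDI2", "10", 860, 720),
        ("NDI3", "11", 750, 705), ("NDI4", "12", 570, 531),
    ]:
        add(name, ND, eq, f"(R{hi}-R{lo})/(R{hi}+R{lo})", _bands(hi, lo),
            lambda b, hi=hi, lo=lo: _nd(b[f"R{hi}"], b[f"R{lo}"]))
    add("NDI5", ND, "13", "(R780-R710)/(R780-R680)", _bands(780, 710, 680),
        lambda b: _div(b["R780"] - b["R710"], b["R780"] - b["R680"]),
        notes="difference denominator as published")
    add("NDI6", ND, "14", "(R850-R710)/(R850-R680)", _bands(850, 710, 680),
        lambda b: _div(b["R850"] - b["R710"], b["R850"] - b["R680"]),
        notes="difference denominator as published")
    add("NDI7", ND, "15", "(R734-R747)/(R715+R726)", _bands(734, 747, 715, 726),
        lambda b: _div(b["R734"] - b["R747"], b["R715"] + b["R726"]))
    add("mNDI", ND, "16", "(R750-R705)/(R750+R705-2*R445)", _bands(750, 705, 445),
        lambda b: _div(b["R750"] - b["R705"],
                       b["R750"] + b["R705"] - 2.0 * b["R445"]))

    # simple ratios (eqs 17-38)
    for name, eq, num, den in [
        ("SR1", "17", 700, 670), ("SR2", "18", 750, 550), ("SR3", "19", 750, 700),
        ("SR4", "20", 780, 670), ("SR5", "21", 787, 765), ("SR6", "22", 553, 537),
        ("SR7", "23", 545, 538), ("SR8", "24", 554, 677), ("SR9", "25", 801, 670),
        ("SR10", "26", 800, 550), ("SR11", "27", 740, 720),
    ]:
        add(name, SRF, eq, f"R{num}/R{den}", _bands(num, den),
            lambda b, num=num, den=den: _div(b[f"R{num}"], b[f"R{den}"]))
    for name, eq, num, d1, d2 in [
        ("SR12", "28", 670, 700, 650),
        ("SR13", "29", 672, 708, 550),
        ("SR14", "30", 860, 708, 550),
    ]:
        add(name, SRF, eq, f"R{num}/(R{d1}*R{d2})", _bands(num, d1, d2),
            lambda b, num=num, d1=d1, d2=d2:
                _div(b[f"R{num}"], b[f"R{d1}"] * b[f"R{d2}"]),
            notes="product denominator as published; original sources may differ")
    add("PSSRa", SRF, "31", "R800/R680", _bands(800, 680),
        lambda b: _div(b["R800"], b["R680"]))
    add("PSSRb", SRF, "32", "R800/R635", _bands(800, 635),
        lambda b: _div(b["R800"], b["R635"]))
    for name, eq, num, den in [
        ("SR15", "33", 750, 705), ("SR16", "34", 950, 660),
        ("SR17", "35", 990, 720), ("SR18", "36", 780, 740),
    ]:
        add(name, SRF, eq, f"R{num}/R{den}", _bands(num, den),
            lambda b, num=num, den=den: _div(b[f"R{num}"], b[f"R{den}"]))
    add("SR19", SRF, "37", "R743'/R1316'", _bands(deriv=(743, 1316)),
        lambda b: _div(b["D743"], b["D1316"]),
        notes="primed bands are first-derivative reflectance")
    add("SR20", SRF, "38", "R730'/R705'", _bands(deriv=(730, 705)),
        lambda b: _div(b["D730"], b["D705"]),
        notes="primed bands are first-derivative reflectance")

    add("ZTM", SRF, "39", "R760/R710", _bands(760, 710),
        lambda b: _div(b["R760"], b["R710"]))
    add("VIopt2", SRF, "40", "R760/R730", _bands(760, 730),
        lambda b: _div(b["R760"], b["R730"]))

    if msr_mode == "canonical":
        msr_expr = "(r-1)/sqrt(r+1), r=%s"
        def _msr(r: float) -> float:
            return _div(r - 1.0, _sqrt(r + 1.0))
    else:
        msr_expr = "(r-1)/(r+1), r=%s"
        def _msr(r: float) -> float:
            return _div(r - 1.0, r + 1.0)
    add("MSR1", SRF, "41", msr_expr % "R800/R670", _bands(800, 670),
        lambda b: _msr(_div(b["R800"], b["R670"])), notes=f"{msr_mode} mode")
    add("MSR2", SRF, "42", msr_expr % "R750/R705", _bands(750, 705),
        lambda b: _msr(_div(b["R750"], b["R705"])), notes=f"{msr_mode} mode")

    add("CARI", "other", "43", "(R700-R670)-0.2*(R700+R550)",
        _bands(700, 670, 550), _cari)
    add("MCARI1", "other", "44", "[(R700-R670)-0.2*(R700-R550)]*(R700/R670)",
        _bands(700, 670, 550), _mcari1)
    add("MCARI2", "other", "45", "[(R750-R705)-0.2*(R750-R550)]*(R750/R705)",
        _bands(750, 705, 550), _mcari2)
    add("TCARI", "other", "46",
        "3*[(R700-R670)-0.2*(R700-R550)*(R700/R670)]",
        _bands(700, 670, 550), _tcari)

    add("TVI", "triangular", "47",
        "0.5*[120*(R750-R550)-200*(R670-R550)]", _bands(750, 670, 550),
        lambda b: 0.5 * (120.0 * (b["R750"] - b["R550"])
                         - 200.0 * (b["R670"] - b["R550"])))
    add("MTVI1", "triangular", "48",
        "1.2*[1.2*(R800-R550)-2.5*(R670-R550)]", _bands(800, 670, 550),
        lambda b: 1.2 * (1.2 * (b["R800"] - b["R550"])
                         - 2.5 * (b["R670"] - b["R550"])))
    add("MTVI2", "triangular", "49",
        "1.5*[1.2*(R800-R550)-2.5*(R670-R550)]"
        "/sqrt((2*R800+1)^2-(6*R800-5*sqrt(R670))-0.5)",
        _bands(800, 670, 550),
        lambda b: _div(
            1.5 * (1.2 * (b["R800"] - b["R550"])
                   - 2.5 * (b["R670"] - b["R550"])),
            _sqrt((2.0 * b["R800"] + 1.0) ** 2
                  - (6.0 * b["R800"] - 5.0 * _sqrt(b["R670"])) - 0.5)))

    if rep_mode == "canonical":
        rep_expr = "710+50*[0.5*(R810+R660)-R710]/(R760-R710)"
        def _rep(b: Bands) -> float:
            return 710.0 + 50.0 * _div(0.5 * (b["R810"] + b["R660"]) - b["R710"],
                                       b["R760"] - b["R710"])
    else:
        rep_expr = "710+50*[0.5*(R810+R660)-R710]/(R760+R710)"
        def _rep(b: Bands) -> float:
            return 710.0 + 50.0 * _div(0.5 * (b["R810"] + b["R660"]) - b["R710"],
                                       b["R760"] + b["R710"])
    add("REP", "red_edge", "50", rep_expr, _bands(810, 760, 710, 660), _rep,
        notes=f"{rep_mode} mode")

    add("OSAVI1", "soil_adjusted", "51",
        "(1+0.16)*(R800-R670)/(R700+R670+0.16)", _bands(800, 700, 670), _osavi1)
    add("OSAVI2", "soil_adjusted", "52",
        "(1+0.16)*(R750-R705)/(R750+R705+0.16)", _bands(750, 705), _osavi2)
    add("MSAVI", "soil_adjusted", "53",
        "0.5*[2*R800+1-sqrt((2*R800+1)^2-8*(R800-R670))]", _bands(800, 670),
        lambda b: 0.5 * (2.0 * b["R800"] + 1.0
                         - _sqrt((2.0 * b["R800"] + 1.0) ** 2
                                 - 8.0 * (b["R800"] - b["R670"]))))
    add("TBI1", "other", "54", "R705/(R717+R491)", _bands(705, 717, 491),
        lambda b: _div(b["R705"], b["R717"] + b["R491"]))
    add("TBI2", "other", "55", "R1310/(R1720+R730)", _bands(1310, 1720, 730),
        lambda b: _div(b["R1310"], b["R1720"] + b["R730"]))
    add("TBI3", "other", "56", "(R924-R703+2*R423)/(R924+R703-2*R423)",
        _bands(924, 703, 423),
        lambda b: _div(b["R924"] - b["R703"] + 2.0 * b["R423"],
                       b["R924"] + b["R703"] - 2.0 * b["R423"]))
    add("R_M", "red_edge", "57", "R750/R720-1", _bands(750, 720),
        lambda b: _div(b["R750"], b["R720"]) - 1.0)
    add("G_M", "other", "58", "R750/R550-1", _bands(750, 550),
        lambda b: _div(b["R750"], b["R550"]) - 1.0)
    add("PNC", "other", "59", "exp[2.5-23.5*(R503-R483)/(R503+R483)]",
        _bands(503, 483),
        lambda b: math.exp(2.5 - 23.5 * _nd(b["R503"], b["R483"])))

    # ratio-of-indices families (eqs 60-62), expanded to 8 members
    ratio_parts = {"TCARI": _tcari, "CARI": _cari,
                   "MCARI1": _mcari1, "MCARI2": _mcari2}
    ratio_eq = {"TCARI": "60", "CARI": "61", "MCARI1": "62", "MCARI2": "62"}
    osavis = {"OSAVI1": _osavi1, "OSAVI2": _osavi2}
    num_bands = {"TCARI": _bands(700, 670, 550), "CARI": _bands(700, 670, 550),
                 "MCARI1": _bands(700, 670, 550),
                 "MCARI2": _bands(750, 705, 550)}
    den_bands = {"OSAVI1": _bands(800, 700, 670), "OSAVI2": _bands(750, 705)}
    for num_name, num_fn in ratio_parts.items():
        for den_name, den_fn in osavis.items():
            bset = dict.fromkeys(num_bands[num_name] + den_bands[den_name])
            add(f"{num_name}_{den_name}", "ratio_of_indices",
                ratio_eq[num_name], f"{num_name}/{den_name}",
                tuple(bset),
                lambda b, nf=num_fn, df=den_fn: _div(nf(b), df(b)))

    names = [d.name for d in defs]
    assert len(names) == len(set(names)) == 67, "catalog must hold 67 unique indices"
    return defs


def resolve_bands(s: Spectrum, d: IndexDefinition) -> Bands:
    """Look up every band the index needs on the given reflectance spectrum."""
    out: Bands = {}
    for center, deriv in d.bands:
        key = ("D%g" if deriv else "R%g") % center
        try:
            out[key] = (derivative_value(s, center) if deriv
                        else band_value(s, center))
        except OutOfRangeError as exc:
            raise OutOfRangeError(f"index {d.name}: {exc}") from exc
    return out


def compute_index(s: Spectrum, d: IndexDefinition) -> float:
    """Evaluate one index on a reflectance spectrum.

    Division by zero or a negative radicand yields NaN (with a warning);
    missing band coverage raises :class:`OutOfRangeError`.
    """
    value = d.fn(resolve_bands(s, d))
    if not np.isfinite(value):
        logger.warning("index %s undefined on spectrum (sentinel emitted)", d.name)
        return UNDEFINED
    return float(value)


def compute_all_indices(samples: list[SampleRecord],
                        catalog: list[IndexDefinition] | None = None,
                        denoise: DenoiseConfig | None = None) -> FeatureTable:
    """Batch-compute the catalog over samples' averaged reflectance spectra.

    Replicates are averaged (and optionally denoised) per sample before
    index evaluation.  Undefined or out-of-coverage values propagate as NaN
    sentinels; a sample without reflectance data yields an all-sentinel row.
    """
    catalog = catalog if catalog is not None else builtin_index_catalog()
    names = [d.name for d in catalog]
    rows = np.full((len(samples), len(catalog)), UNDEFINED)
    for i, rec in enumerate(samples):
        if not rec.reflectance_reps:
            logger.warning("sample %s has no reflectance replicates; "
                           "emitting sentinel row", rec.sample_id)
            continue
        spec = average_replicates(rec.reflectance_reps)
        if denoise is not None and denoise.enabled:
            spec = wavelet_denoise(spec, denoise)
        for j, d in enumerate(catalog):
            try:
                rows[i, j] = compute_index(spec, d)
            except OutOfRangeError:
                logger.warning("sample %s: %s lacks band coverage; sentinel",
                               rec.sample_id, d.name)
    return FeatureTable([r.sample_id for r in samples], names, rows)
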