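"""Unit conversion and assembly of the three-system energy profile.

Liters of O2 are the canonical store; kilojoules and kilocalories are always
derived through the fixed caloric equivalents 20.9 kJ·L⁻¹ and 5 kcal·L⁻¹ —
never stored independently, so the three units can never drift apart.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

KJ_PER_LO2 = 20.9
KCAL_PER_LO2 = 5.0

_SYSTEMS = ("aerobic", "alactic", "lactic")


@dataclass(frozen=True)
class EnergyAmount:
    """An energy quantity; kJ and kcal are derived from the canonical L O2."""

    lo2: float

    @property
    def kj(self) -> float:
        return self.lo2 * KJ_PER_LO2

    @property
    def kcal(self) -> float:
        return self.lo2 * KCAL_PER_LO2


def to_energy(lo2: float) -> EnergyAmount:
    """Wrap a liters-of-O2 value as an :class:`EnergyAmount`."""
    return EnergyAmount(float(lo2))


@dataclass(frozen=True)
class EnergyProfile:
    """The assembled aerobic / anaerobic-alactic / anaerobic-lactic profile.

    Percentages are ``None`` when the total is not positive. ``computed``
    records which systems were actually calculated (a skipped system enters
    the total as 0 and is marked "not computed" in reports).
    """

    a_met: EnergyAmount
    al_met: EnergyAmount
    la_met: EnergyAmount
    total: EnergyAmount
    pct_a: float | None
    pct_al: float | None
    pct_la: float | None
    computed: tuple[str, ...] = _SYSTEMS
    warnings: tuple[str, ...] = ()


def assemble_profile(
    a: float,
    al: float,
    la: float,
    computed: tuple[str, ...] = _SYSTEMS,
    warnings: tuple[str, ...] = (),
) -> EnergyProfile:
    """Assemble component volumes (liters of O2) into a full profile.

    The total is the sum of the three systems; percentages are reported only
    when the total is positive, otherwise a warning is attached.
    """
    total = a + al + la
    warn = list(warnings)
    unknown = set(computed) - set(_SYSTEMS)
    if unknown:
        raise ValueError(f"unknown system name(s): {sorted(unknown)}")
    if total > 0:
        pct_a, pct_al, pct_la = (100.0 * x / total for x in (a, al, la))
    else:
        pct_a = pct_al = pct_la = None
        warn.append("total energy is not positive; percentages omitted")
    return EnergyProfile(
        a_met=to_energy(a),
        al_met=to_energy(al),
        la_met=to_energy(la),
        total=to_energy(total),
        pct_a=pct_a,
        pct_al=pct_al,
        pct_la=pct_la,
        computed=tuple(computed),
        warnings=tuple(warn),
    )


def _amount_dict(amount: EnergyAmount) -> dict:
    return {"lo2": amount.lo2, "kj": amount.kj, "kcal": amount.kcal}


def profile_to_dict(profile: EnergyProfile) -> dict:
    """Full-precision dictionary rendering (the JSON report body)."""
    return {
        "aerobic": _amount_dict(profile.a_met),
        "alactic": _amount_dict(profile.al_met),
        "lactic": _amount_dict(profile.la_met),
        "total": _amount_dict(profile.total),
        "percent": {
            "aerobic": profile.pct_a,
            "alactic": profile.pct_al,
            "lactic": profile.pct_la,
        },
        "computed": list(profile.computed),
        "warnings": list(profile.warnings),
    }


def render_json(profile: EnergyProfile, extra: dict | None = None) -> str:
    """Deterministic JSON report; values kept at full precision."""
    doc = profile_to_dict(profile)
    if extra:
        doc.update(extra)
    return json.dumps(doc, indent=2, sort_keys=True)


def render_table(profile: EnergyProfile, precision: int = 1) -> str:
    """Human-readable aligned table, rounded to ``precision`` decimals."""
    rows = [
        ("Aerobic", profile.a_met, profile.pct_a, "aerobic"),
        ("Anaerobic lactic", profile.la_met, profile.pct_la, "lactic"),
        ("Anaerobic alactic", profile.al_met, profile.pct_al, "alactic"),
        ("Total", profile.total, None, None),
    ]
    p = precision
    lines = [
        f"{'System':<20}{'L O2':>10}{'kJ':>10}{'kcal':>10}{'%':>8}",
    ]
    for label, amount, pct, key in rows:
        if key is not None and key not in profile.computed:
            lines.append(f"{label:<20}{'(not computed)':>38}")
            continue
        pct_s = f"{pct:.{p}f}" if pct is not None else "-"
        lines.append(
            f"{label:<20}{amount.lo2:>10.{p}f}{amount.kj:>10.{p}f}"
            f"{amount.kcal:>10.{p}f}{pct_s:>8}"
        )
    for w in profile.warnings:
        lines.append(f"warning: {w}")
    return "\n".join(lines)


def render_tsv(profile: EnergyProfile) -> str:
    """Machine-friendly TSV export at full precision."""
    header = "system\tlo2\tkj\tkcal\tpercent\tcomputed"
    rows = [header]
    for key, amount, pct in (
        ("aerobic", profile.a_met, profile.pct_a),
        ("alactic", profile.al_met, profile.pct_al),
        ("lactic", profile.la_met, profile.pct_la),
    ):
        rows.append(
            f"{key}\t{amount.lo2!r}\t{amount.kj!r}\t{amount.kcal!r}"
            f"\t{pct if pct is None else repr(pct)}\t{key in profile.computed}"
        )
    rows.append(
        f"total\t{profile.total.lo2!r}\t{profile.total.kj!r}"
        f"\t{profile.total.kcal!r}\t\t"
    )
    return "\n".join(rows)
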