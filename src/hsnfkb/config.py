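"""Reading and writing the model's parameter/equation config.

The config is a TOML file with three blocks: ``[species]`` (the 31 state
variables with descriptions), ``[parameters]`` (the 60 kinetic
parameters, each with value, unit, pathway tag and module group),
``[[reactions]]`` (the declarative reaction registry) plus ``[totals]``
and ``[structural]``.  Loading validates the species and parameter
counts against the model's declared size (31 equations, 60 parameters)
and write→read round-trips are lossless.
"""

from __future__ import annotations

import tomllib
from importlib import resources
from pathlib import Path

from .params import (HILL_N, MODULE_GROUPS, N_PARAMS, PARAM_ORDER,
                     PATHWAY_TAGS, ParameterError, ParameterSet,
                     TOTAL_NAMES)
from .reactions import REACTIONS
from .species import N_SPECIES, SPECIES_NAMES

__all__ = ["load_parameter_config", "save_parameter_config",
           "default_parameters", "default_config_path"]

#: units of each kinetic parameter (per-molecule rates are 1/(molecule·h))
PARAM_UNITS: dict[str, str] = {}
for _k in PARAM_ORDER:
    if _k in ("K_hill", "K_protect", "K_a20_tnf", "K_a20_il1"):
        PARAM_UNITS[_k] = "molecules"
    elif _k in ("T_mid", "w_den"):
        PARAM_UNITS[_k] = "degC"
    elif _k in ("k_mrna_basal", "k_mrna_max", "k_ikba_txn_basal",
                "k_a20_txn_basal"):
        PARAM_UNITS[_k] = "molecules/h"
    elif _k in ("k_hsf_hspi_on", "k_bind_hspi_tnf", "k_bind_hspc_il1",
                "k_bind_hspc_ikk", "k_assoc_cyt", "k_assoc_nuc",
                "k_phos_free", "k_phos_complex", "k_ikk_act_tnf",
                "k_ikk_act_il1", "k_ikk_inact_hsp", "k_ikk_reset_hsp",
                "k_detrimer_hsp", "k_ikba_txn", "k_a20_txn"):
        PARAM_UNITS[_k] = "1/(molecule*h)"
    elif _k == "k_trimer":
        PARAM_UNITS[_k] = "1/(molecule^2*h)"
    else:
        PARAM_UNITS[_k] = "1/h"

SPECIES_DESCRIPTIONS: dict[str, str] = {
    "HSF1": "free HSF1 monomer",
    "HSF1_HSPI": "inactive HSF1:HSPi complex",
    "HSF1_3": "active HSF1 trimer",
    "M_HSPI": "HSPi mRNA",
    "HSPI": "free inducible chaperone",
    "HSPC": "free constitutive chaperone",
    "HSPI_IKKKT_D": "HSPi bound to denatured IKKK_TNF",
    "HSPC_IKKKI_D": "HSPc bound to denatured IKKK_IL1",
    "HSPC_IKK_D": "HSPc bound to denatured IKK",
    "R_TNF": "active TNF receptor fraction",
    "R_IL1": "active IL1 receptor fraction",
    "IKKKT_N": "IKKK_TNF neutral",
    "IKKKT_A": "IKKK_TNF active",
    "IKKKT_D": "IKKK_TNF denatured (insoluble)",
    "IKKKI_N": "IKKK_IL1 neutral",
    "IKKKI_A": "IKKK_IL1 active",
    "IKKKI_D": "IKKK_IL1 denatured (insoluble)",
    "IKK_N": "IKK neutral (soluble)",
    "IKK_A": "IKK active",
    "IKK_I": "IKK inactive (refractory)",
    "IKK_D": "IKK denatured (insoluble)",
    "NFKB_C": "free cytoplasmic NF-kB",
    "NFKB_N": "free nuclear NF-kB",
    "IKBA_C": "free cytoplasmic IkBa",
    "IKBA_N": "free nuclear IkBa",
    "IKBA_NFKB_C": "cytoplasmic IkBa:NF-kB complex",
    "IKBA_NFKB_N": "nuclear IkBa:NF-kB complex",
    "P_IKBA_NFKB": "phospho-IkBa:NF-kB complex",
    "M_IKBA": "IkBa mRNA",
    "M_A20": "A20 mRNA",
    "A20": "A20 protein",
}


class ConfigError(ValueError):
    """Raised when a parameter config fails structural validation."""


def default_config_path() -> Path:
    return Path(str(resources.files("hsnfkb").joinpath(
        "data/model_config.toml")))


def load_parameter_config(path: str | Path | None = None
                          ) -> tuple[ParameterSet, list[dict]]:
    """Load a parameter config; returns (ParameterSet, reaction registry).

    Validates that the file declares exactly 31 species and 60 kinetic
    parameters, that every name is known, every value numeric and
    non-negative, and that every reaction references known species and
    parameters.
    """
    path = Path(path) if path is not None else default_config_path()
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)

    species = doc.get("species", {})
    if set(species) != set(SPECIES_NAMES):
        missing = sorted(set(SPECIES_NAMES) - set(species))
        extra = sorted(set(species) - set(SPECIES_NAMES))
        raise ConfigError(
            f"species block must list exactly the {N_SPECIES} model "
            f"state variables; missing={missing} unknown={extra}")

    raw_params = doc.get("parameters", {})
    if set(raw_params) != set(PARAM_ORDER):
        missing = sorted(set(PARAM_ORDER) - set(raw_params))
        extra = sorted(set(raw_params) - set(PARAM_ORDER))
        raise ConfigError(
            f"parameters block must list exactly the {N_PARAMS} kinetic "
            f"parameters; missing={missing} unknown={extra}")
    values: dict[str, float] = {}
    for key, entry in raw_params.items():
        v = entry.get("value") if isinstance(entry, dict) else entry
        if not isinstance(v, (int, float)) or isinstance(v, bool):
            raise ConfigError(f"parameter {key!r} has non-numeric value")
        if v < 0:
            raise ConfigError(f"parameter {key!r} is negative: {v}")
        values[key] = float(v)

    totals = {k: float(v) for k, v in doc.get("totals", {}).items()}
    hill_n = doc.get("structural", {}).get("hill_n", HILL_N)

    reactions = doc.get("reactions", [])
    known_species = set(SPECIES_NAMES)
    for rx in reactions:
        for s in (list(rx.get("reactants", [])) +
                  list(rx.get("products", [])) +
                  list(rx.get("modifiers", []))):
            if s not in known_species:
                raise ConfigError(
                    f"reaction {rx.get('name')!r} references unknown "
                    f"species {s!r}")
        for p in rx.get("parameters", []):
            if p not in PARAM_ORDER:
                raise ConfigError(
                    f"reaction {rx.get('name')!r} references unknown "
                    f"parameter {p!r}")

    try:
        ps = ParameterSet(values=values, totals=totals, hill_n=hill_n)
    except ParameterError as exc:
        raise ConfigError(str(exc)) from exc
    return ps, list(reactions)


def _fmt(v: float) -> str:
    if isinstance(v, int) or float(v).is_integer():
        return repr(float(v))
    return repr(float(v))


def save_parameter_config(params: ParameterSet, path: str | Path,
                          reactions: list[dict] | None = None) -> None:
    """Write a config that :func:`load_parameter_config` reads back
    identically."""
    reactions = REACTIONS if reactions is None else reactions
    lines: list[str] = []
    lines.append("# Combined HSR / NF-kB model configuration")
    lines.append("# 31 state variables, 60 kinetic parameters")
    lines.append("")
    lines.append("[structural]")
    lines.append(f"hill_n = {params.hill_n}")
    lines.append("")
    lines.append("[totals]  # nominal conserved totals, molecules/cell")
    for k in TOTAL_NAMES:
        lines.append(f"{k} = {_fmt(params.totals[k])}")
    lines.append("")
    lines.append("[species]")
    for name in SPECIES_NAMES:
        lines.append(f'{name} = "{SPECIES_DESCRIPTIONS[name]}"')
    lines.append("")
    lines.append("[parameters]")
    for key in PARAM_ORDER:
        lines.append(
            f'{key} = {{ value = {_fmt(params.values[key])}, '
            f'unit = "{PARAM_UNITS[key]}", '
            f'pathway = "{PATHWAY_TAGS[key]}", '
            f'group = "{MODULE_GROUPS[key]}" }}')
    lines.append("")
    for rx in reactions:
        lines.append("[[reactions]]")
        lines.append(f'name = "{rx["name"]}"')
        for fld in ("reactants", "products", "modifiers", "parameters"):
            items = rx.get(fld, [])
            quoted = ", ".join(f'"{x}"' for x in items)
            lines.append(f"{fld} = [{quoted}]")
        lines.append(f'rate_law = "{rx["rate_law"]}"')
        lines.append("")
    Path(path).write_text("\n".join(lines))


def default_parameters() -> ParameterSet:
    """The shipped, calibrated parameter set."""
    return load_parameter_config()[0]
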