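"""Reading rating tables, serializing reports, fixture generation, config files.

Input is a wide CSV/TSV table: rows = subjects, columns = raters, cells =
category labels.  The delimiter is inferred from the file extension (``.tsv``
/ ``.tab`` / ``.txt`` -> tab, otherwise comma).  Default missing codes are
the empty string, ``NA`` and ``.``.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .exceptions import ValidationError
from .model import AgreementResults, InterRaterReliability
from .ratings import RatingTable

SPEC_VERSION = "1.0"
DEFAULT_MISSING_CODES = ("", "NA", ".")


def _delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_ratings(
    path,
    missing_codes=DEFAULT_MISSING_CODES,
    categories=None,
    scale: str = "nominal",
    header: bool = False,
    transpose: bool = False,
) -> RatingTable:
    """Read a wide CSV/TSV rating table into a :class:`RatingTable`.

    ``categories`` fixes the label order (mandatory for ordinal scales);
    ``transpose`` flips a raters-by-subjects layout.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    try:
        df = pd.read_csv(
            path,
            sep=_delimiter(path),
            header=0 if header else None,
            dtype=str,
            keep_default_na=False,
            skip_blank_lines=True,
            engine="python",
        )
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed table in {path}: {exc}") from exc
    if df.isna().any().any():
        raise ValidationError(f"ragged rows in {path}: not every row has the same length")
    if transpose:
        df = df.T
    if df.empty:
        raise ValidationError(f"{path} contains no data rows")
    model = InterRaterReliability.from_dataframe(
        df, categories=categories, missing_codes=missing_codes, scale=scale
    )
    table = model.ratings
    if table.n_missing == table.n_subjects * table.n_raters:
        raise ValidationError(f"{path} contains only missing values")
    return table


def write_ratings(table: RatingTable, path) -> None:
    """Write a rating table as CSV/TSV using its original labels ('' for missing)."""
    path = Path(path)
    labels = [
        ["" if v == 0 else table.label_of(int(v)) for v in row] for row in table.values
    ]
    pd.DataFrame(labels).to_csv(path, sep=_delimiter(path), header=False, index=False)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def build_report(results: AgreementResults, input_path: str | None = None) -> dict:
    """A JSON-serializable report: estimates, CIs, accounting and settings echo."""
    rt = results.model.ratings
    report = {
        "spec_version": SPEC_VERSION,
        "package_version": __version__,
        "input": str(input_path) if input_path else None,
        "data": {
            "n_subjects": rt.n_subjects,
            "n_raters": rt.n_raters,
            "k_categories": rt.k,
            "scale": rt.scale,
            "categories": list(rt.categories) if rt.categories else None,
            "missing_cells": rt.n_missing,
        },
        "settings": {
            "level": results.settings.level,
            "n_boot": results.settings.n_boot,
            "seed": results.settings.seed if isinstance(results.settings.seed, int) else None,
        },
        "estimates": {},
    }
    for measure, est in results.estimates.items():
        entry = {
            "value": est.value,
            "degenerate": est.degenerate_flag,
            "subjects_used": est.n_subjects_used,
            "subjects_excluded": rt.n_subjects - est.n_subjects_used,
            "confidence_intervals": {},
        }
        for (m, method), ci in results.conf_ints.items():
            if m == measure:
                entry["confidence_intervals"][method] = {
                    "lower": ci.lower,
                    "upper": ci.upper,
                    "level": ci.level,
                }
        report["estimates"][measure] = entry
    if results.fleiss_se is not None:
        report["estimates"]["fleiss_k"]["standard_error"] = results.fleiss_se
    return report


def report_roundtrip(report: dict) -> dict:
    return json.loads(json.dumps(report))


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def write_fixtures(out_dir, seed: int = 20160805) -> list[Path]:
    """Write small reference tables with sidecar files of expected estimates.

    * ``worked_example`` — four subjects, two raters: K = 0.466667,
      alpha = 0.533333.
    * ``perfect_agreement`` / ``inverse_agreement`` — the two boundary cases.
    * ``case_study_nominal`` / ``case_study_ordinal`` — synthetic 50 x 4
      tables shaped like a histopathology re-reading study (four categories,
      10 % MCAR missingness); the ordinal one has disagreements clustered on
      adjacent ranks.  Their sidecars are computed, not analytic.
    """
    from .estimators import alpha_from_ratings, fleiss_k_from_ratings
    from .simulate import MissingDesign, apply_mcar, make_scenario, latent_class_sample

    import numpy as np

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, table: RatingTable, expected: dict) -> None:
        csv_path = out / f"{name}.csv"
        write_ratings(table, csv_path)
        sidecar = out / f"{name}.expected.json"
        sidecar.write_text(json.dumps(expected, indent=2) + "\n")
        written.extend([csv_path, sidecar])

    worked = RatingTable(
        values=np.array([[1, 1], [1, 1], [2, 2], [1, 2]]), k=2, categories=("1", "2")
    )
    emit(
        "worked_example",
        worked,
        {
            "fleiss_k": round(fleiss_k_from_ratings(worked).value, 6),
            "krippendorff_alpha": round(alpha_from_ratings(worked).value, 6),
        },
    )

    perfect = RatingTable(
        values=np.tile(np.array([[1], [2], [1], [2], [1]]), (1, 3)), k=2,
        categories=("1", "2"),
    )
    emit("perfect_agreement", perfect, {"fleiss_k": 1.0, "krippendorff_alpha": 1.0})

    n_inv = 10
    inverse = RatingTable(
        values=np.tile(np.array([[1, 2]]), (n_inv, 1)), k=2, categories=("1", "2")
    )
    emit(
        "inverse_agreement",
        inverse,
        {
            "fleiss_k": -1.0,
            "krippendorff_alpha": -(n_inv - 1) / n_inv,  # 1 - D_o/D_e at n.. = 2N
        },
    )

    # Case-study-shaped synthetic tables: 50 biopsies x 4 raters, k = 4.
    scen = make_scenario(N=50, n_raters=4, k=4, agreement="moderate",
                         pi=(0.2, 0.25, 0.25, 0.3))
    rng = np.random.default_rng(seed)
    complete = latent_class_sample(scen, rng)
    nominal = apply_mcar(complete, MissingDesign(0.10), rng)
    emit(
        "case_study_nominal",
        nominal,
        {
            "fleiss_k": fleiss_k_from_ratings(nominal).value,
            "krippendorff_alpha": alpha_from_ratings(nominal).value,
        },
    )

    # Ordinal variant: raters err to adjacent ranks, so ordinal alpha > nominal.
    latent = rng.integers(1, 5, size=50)
    shift = rng.choice([-1, 0, 0, 1], size=(50, 4))
    ordinal_values = np.clip(latent[:, None] + shift, 1, 4)
    ordinal_complete = RatingTable(
        values=ordinal_values, k=4, scale="ordinal", categories=("1", "2", "3", "4")
    )
    ordinal = apply_mcar(ordinal_complete, MissingDesign(0.10), rng)
    emit(
        "case_study_ordinal",
        ordinal,
        {
            "krippendorff_alpha_ordinal": alpha_from_ratings(ordinal).value,
            "krippendorff_alpha_nominal": alpha_from_ratings(
                RatingTable(values=ordinal.values, k=4, scale="nominal",
                            categories=ordinal.categories)
            ).value,
        },
    )
    return written


# ---------------------------------------------------------------------------
# Simulation config
# ---------------------------------------------------------------------------

def load_sim_config(path) -> dict:
    """Load simulation overrides (runs, n_boot, seed, grid, scenarios) from YAML."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError("simulation config must be a mapping")
    allowed = {"runs", "n_boot", "seed", "grid", "scenarios", "level", "methods"}
    unknown = set(cfg) - allowed
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return cfg
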