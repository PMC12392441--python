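"""Synthetic peak-table generator.

Emulates the peak tables produced by reducing an HPLC-CAD-HRMS oligomer
chromatogram: an ensemble is simulated to a known true scission extent,
per-oligomer wt% inside the resolved MW window becomes one mass-
proportional integral per oligomer, the mass outside the window is lumped
into single low-MW and high-MW rows, and every integral is perturbed by
multiplicative lognormal noise.  The true extent is written to a sidecar
metadata file, never into the table itself, so recovery experiments stay
blind.

The generator reproduces the censored-window structure and the mass-
proportional detector response of real data.  It does not emulate
chromatographic co-elution, MS adduct chemistry, end-group mass shifts or
baseline drift, so recovery performance on these fixtures bounds, rather
than guarantees, performance on real chromatograms.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble import ChainEnsemble, EnsembleSpec, RateModel, build_initial_ensemble
from .errors import ValidationError
from .peaks import (
    DEFAULT_CENSOR_BOUNDS,
    KIND_LUMP_HIGH,
    KIND_LUMP_LOW,
    KIND_RESOLVED,
    PeakTable,
    write_peak_table,
)
from .simulate import run_simulation


def _default_spec() -> EnsembleSpec:
    return EnsembleSpec.from_mw(m=5000, mn0_da=6380.0, sigma_da=400.0)


def generate_fixture_peak_table(
    true_sic: float,
    noise_rel: float = 0.0,
    censor_bounds: tuple[float, float] = DEFAULT_CENSOR_BOUNDS,
    seed: int = 0,
    spec: EnsembleSpec | None = None,
    model: RateModel | None = None,
    path: str | Path | None = None,
) -> tuple[PeakTable, dict]:
    """Generate a synthetic peak table with known true scission extent.

    Parameters
    ----------
    true_sic : float
        Scission extent the ensemble is simulated to (0 = unreacted).
    noise_rel : float
        Sigma of the multiplicative lognormal perturbation applied to each
        integral (0 = noise-free); must be < 0.5.
    censor_bounds : (low, high)
        Resolved window in Da; mass strictly below/above is lumped.
    seed : int
        Drives both the simulation and the noise.
    path : optional
        If given, the table is written to ``<path>`` as CSV and the truth
        to a ``<path>.meta.json`` sidecar.

    Returns
    -------
    (PeakTable, metadata dict); the metadata holds the truth and all
    generator parameters.
    """
    if true_sic < 0:
        raise ValidationError(f"true_sic must be nonnegative, got {true_sic!r}")
    if not 0 <= noise_rel < 0.5:
        raise ValidationError(f"noise_rel must be in [0, 0.5), got {noise_rel!r}")
    low, high = censor_bounds
    if not low < high:
        raise ValidationError(f"censor bounds must be increasing, got {censor_bounds!r}")
    if spec is None:
        spec = _default_spec()
    if model is None:
        model = RateModel()

    sim_seed_seq, noise_seed_seq = np.random.SeedSequence(seed).spawn(2)
    sim_seed = int(sim_seed_seq.generate_state(1)[0])
    if true_sic == 0:
        ensemble: ChainEnsemble = build_initial_ensemble(spec, seed=sim_seed)
    else:
        ensemble = run_simulation(
            spec, model, sic_target=true_sic, seed=sim_seed
        ).final_ensemble

    lengths, counts = ensemble.lengths_and_counts()
    mw = lengths * ensemble.mw_monomer
    mass = (lengths * counts).astype(float)
    wt_pct = mass / mass.sum() * 100.0

    in_window = (mw >= low) & (mw <= high)
    rows = [
        {"kind": KIND_LUMP_LOW, "mw_da": np.nan, "integral": float(wt_pct[mw < low].sum())},
        *(
            {"kind": KIND_RESOLVED, "mw_da": float(m), "integral": float(w)}
            for m, w in zip(mw[in_window], wt_pct[in_window])
        ),
        {"kind": KIND_LUMP_HIGH, "mw_da": np.nan, "integral": float(wt_pct[mw > high].sum())},
    ]
    df = pd.DataFrame(rows)
    if noise_rel > 0:
        rng = np.random.default_rng(noise_seed_seq)
        df["integral"] = df["integral"] * np.exp(
            rng.normal(0.0, noise_rel, size=len(df))
        )
    table = PeakTable(df)
    meta = {
        "true_sic": true_sic,
        "noise_rel": noise_rel,
        "censor_bounds": list(censor_bounds),
        "seed": seed,
        "spec": asdict(spec),
        "model": asdict(model),
    }
    if path is not None:
        path = Path(path)
        write_peak_table(table, path)
        with open(f"{path}.meta.json", "w") as fh:
            json.dump(meta, fh, indent=2)
    return table, meta
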