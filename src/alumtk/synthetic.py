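"""Synthetic study-like datasets with the structure of the curated ²⁶Al data.

The generator emulates the statistical shape of the multi-study tracer
dataset the model was calibrated on: intravenous and oral dosing of citrate
and chloride salts in rats and humans, heterogeneous reporting units (fid,
g/L, fid/g, ...), per-individual human time series versus per-study rat
groups, log-normal residual error, and mean ± sd summary rows for a subset
of rat studies.  It exists so that curation, population simulation and
parameter estimation are testable end-to-end without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .physiology import InvalidInputError, ReferenceIndividual
from .model import DoseEvent, PBTKParameters, simulate
from .curation import (MIN_TIME_H, MOLAR_MASS_AL26, StudyIdentifier,
                       curate_dataset, fid_to_unit, parse_identifier)
from .population import PopulationModel, default_population, resolve_reference, sample_individual

__all__ = [
    "StudyDesign",
    "GroundTruth",
    "default_designs",
    "generate_dataset",
    "roundtrip_check",
]


@dataclass(frozen=True)
class StudyDesign:
    """Design of one synthetic study (rat) or individual series (human).

    ``sampling_times`` maps matrix → times in hours (> 1 s); ``units`` maps
    matrix → reporting unit.  ``aggregate`` emits mean ± sd rows of the
    ``n_subjects`` values instead of individual rows (rats only in the
    default set).  Urine reported in g/L uses per-interval collections of
    ``collected_volume_L``.
    """

    identifier: str
    n_subjects: int
    sampling_times: Mapping[str, tuple[float, ...]]
    units: Mapping[str, str]
    dose_mol_per_kg: float
    aggregate: bool = False
    sex: str | None = None
    collected_volume_L: float = 1.5

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise InvalidInputError("n_subjects must be at least 1")
        if self.aggregate and self.n_subjects < 2:
            raise InvalidInputError("aggregate designs need n_subjects >= 2")
        if self.dose_mol_per_kg <= 0:
            raise InvalidInputError("dose must be positive")
        for mat, times in self.sampling_times.items():
            if mat not in self.units:
                raise InvalidInputError(f"no reporting unit for matrix {mat!r}")
            if any(t <= MIN_TIME_H for t in times):
                raise InvalidInputError(f"sampling times for {mat!r} must exceed 1 s")

    @property
    def parsed(self) -> StudyIdentifier:
        return parse_identifier(self.identifier)


@dataclass
class GroundTruth:
    """Generating population model plus the per-group sampled parameters."""

    population: PopulationModel
    parameters: dict[str, PBTKParameters]
    references: dict[str, ReferenceIndividual]
    doses: dict[str, list[DoseEvent]]
    t_grids: dict[str, np.ndarray] = field(default_factory=dict)

    def predict_fid(self, group_id: str, matrix: str, times) -> np.ndarray:
        """Noise-free whole-compartment fid of a group at given times.

        Evaluation reuses the group's generation time grid (plus any extra
        requested times) so that predictions at generation times reproduce
        the generated noise-free values exactly.
        """
        times = np.atleast_1d(np.asarray(times, dtype=float))
        base = self.t_grids.get(group_id, np.array([0.0]))
        t_grid = np.unique(np.concatenate([[0.0], base, times]))
        res = simulate(self.parameters[group_id], self.references[group_id],
                       self.doses[group_id], t_grid)
        series = res.series(matrix)
        idx = np.searchsorted(t_grid, times)
        return series[idx]


def default_designs() -> list[StudyDesign]:
    """Package-default synthetic design: 6 rat studies + 8 human individuals.

    Mirrors the curated dataset's qualitative proportions — mixed routes and
    salts, fid as the most common reporting unit followed by g/L, early
    blood sampling and terminal tissue sampling, long bone follow-up in two
    studies, and about a quarter of the records emitted as mean ± sd rows.
    """
    early = (0.5, 1.0, 2.0, 4.0, 8.0, 24.0)
    rat = [
        StudyDesign("RatIvCit2020-AlCit-iv-rat-250g", 5,
                    {"pla": (0.25, 0.5, 1, 2, 4, 8, 24),
                     "liv": (24, 120, 672), "spl": (24, 120, 672),
                     "bon": (24, 672), "uri": (24, 48, 120)},
                    {"pla": "fid", "liv": "fid", "spl": "fid",
                     "bon": "fid_per_g", "uri": "fid"},
                    dose_mol_per_kg=2e-6),
        StudyDesign("RatIvChl2019-AlChl-iv-rat-300g", 6,
                    {"pla": (0.25, 0.5, 1, 2, 4, 8, 24),
                     "liv": (24, 168, 1000, 5000), "mus": (24, 168, 1000),
                     "bon": (24, 168, 1000, 5000, 7000), "bra": (168, 1000, 5000),
                     "uri": (24, 48, 168)},
                    {"pla": "g_per_L", "liv": "fid", "mus": "fid",
                     "bon": "fid", "bra": "fid", "uri": "fid"},
                    dose_mol_per_kg=2e-6),
        StudyDesign("RatPoChl2018-AlChl-po-rat-250g", 8,
                    {"blo": early, "liv": (24, 168), "bon": (24, 168, 672),
                     "uri": (24, 48)},
                    {"blo": "fid", "liv": "fid", "bon": "fid", "uri": "fid"},
                    dose_mol_per_kg=8e-6),
        StudyDesign("RatPoCit2017-AlCit-po-rat-280g", 6,
                    {"blo": early, "bon": (24, 168, 672), "uri": (24, 48)},
                    {"blo": "fid", "bon": "fid_per_g", "uri": "fid"},
                    dose_mol_per_kg=7e-6),
        StudyDesign("RatPoChl2016-AlChl-po-rat-fasted-275g", 8,
                    {"blo": (1, 2, 4, 8, 24), "liv": (24, 168),
                     "spl": (24, 168), "bon": (168, 1000, 4000)},
                    {"blo": "fid", "liv": "fid", "spl": "fid", "bon": "fid"},
                    dose_mol_per_kg=7e-6, aggregate=True),
        StudyDesign("RatPoChl2015-AlChl-po-rat-hardwater-480g", 6,
                    {"blo": (1, 2, 4, 8, 24), "bon": (24, 672, 2000),
                     "kid": (24, 672)},
                    {"blo": "fid", "bon": "percent_dose_per_kg", "kid": "fid"},
                    dose_mol_per_kg=6e-6, aggregate=True),
    ]
    human_iv_pla = (1, 2, 4, 8, 24, 48, 168, 504, 1512, 3024)
    human = [
        StudyDesign("HumIvCit2021-AlCit-iv-hum-73kg", 1,
                    {"pla": human_iv_pla, "uri": (24, 48, 168, 504)},
                    {"pla": "fid", "uri": "fid"}, dose_mol_per_kg=2e-7, sex="male"),
        StudyDesign("HumIvCit2021-AlCit-iv-hum-79kg", 1,
                    {"pla": human_iv_pla, "uri": (24, 48, 168, 504)},
                    {"pla": "g_per_L", "uri": "fid"}, dose_mol_per_kg=2e-7, sex="male"),
        StudyDesign("HumIvCit2020-AlCit-iv-hum-60kg", 1,
                    {"pla": human_iv_pla, "uri": (24, 168)},
                    {"pla": "fid", "uri": "fid"}, dose_mol_per_kg=1e-7, sex="female"),
        StudyDesign("HumIvCit2019-AlCit-iv-hum-84kg", 1,
                    {"pla": human_iv_pla, "bon": (3024, 5040)},
                    {"pla": "fid", "bon": "fid_per_g"}, dose_mol_per_kg=3e-7, sex="male"),
        StudyDesign("HumIvChl2018-AlChl-iv-hum-79kg", 1,
                    {"pla": (1, 2, 4, 8, 24, 48, 168, 504), "uri": (24, 168)},
                    {"pla": "fid", "uri": "fid"}, dose_mol_per_kg=2e-7, sex="male"),
        StudyDesign("HumPoChl2017-AlChl-po-hum-73kg", 1,
                    {"blo": (0.5, 1, 2, 3, 4, 6, 8, 12, 24), "uri": (24, 48)},
                    {"blo": "fid", "uri": "fid"}, dose_mol_per_kg=1e-6, sex="male"),
        StudyDesign("HumPoChl2016-AlChl-po-hum-62kg", 1,
                    {"blo": (0.5, 1, 2, 3, 4, 6, 8, 12, 24)},
                    {"blo": "g_per_L"}, dose_mol_per_kg=1e-6, sex="female"),
        StudyDesign("HumPoCit2015-AlCit-po-hum-73kg", 1,
                    {"blo": (0.5, 1, 2, 4, 8, 24), "uri": (24,)},
                    {"blo": "fid", "uri": "fid"}, dose_mol_per_kg=1e-6, sex="male"),
    ]
    return rat + human


def designs_from_file(path) -> list[StudyDesign]:
    """Load study designs from a YAML list of mappings.

    Each entry mirrors the :class:`StudyDesign` fields, e.g.::

        - identifier: RatX2020-AlChl-po-rat-250g
          n_subjects: 4
          sampling_times: {blo: [1, 4, 24]}
          units: {blo: fid}
          dose_mol_per_kg: 5.0e-6
          aggregate: false
    """
    import yaml

    with open(path) as fh:
        entries = yaml.safe_load(fh) or []
    designs = []
    for entry in entries:
        entry = dict(entry)
        entry["sampling_times"] = {m: tuple(v) for m, v in entry["sampling_times"].items()}
        designs.append(StudyDesign(**entry))
    return designs


def _subject_groups(design: StudyDesign) -> list[str]:
    """Group keys: humans get one group per subject, rats one per study."""
    ident = design.parsed
    if ident.species == "hum" and design.n_subjects > 1:
        return [f"{design.identifier}#{i + 1}" for i in range(design.n_subjects)]
    return [design.identifier]


def generate_dataset(designs: Sequence[StudyDesign] | None = None,
                     pop: PopulationModel | None = None, seed=0,
                     ) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate an observation table (curation CSV dialect) plus ground truth.

    For every group a parameter set is sampled from ``pop`` (rat subjects
    share their study's draw; each human subject is an individual draw);
    the model is simulated, matrix values read off at the design's sampling
    times, converted from fid to the reporting unit with the group's
    reference individual, and perturbed by log-normal residual error.
    Aggregate designs replace per-subject rows by (N, mean, sd) rows.
    Deterministic for a given seed.
    """
    if designs is None:
        designs = default_designs()
    if pop is None:
        pop = default_population()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    rows = []
    truth = GroundTruth(population=pop, parameters={}, references={}, doses={})
    for design in designs:
        ident = design.parsed
        ref = resolve_reference(ident.species, ident.body_weight_kg, design.sex)
        dose_total_mol = design.dose_mol_per_kg * ident.body_weight_kg
        dose_g = dose_total_mol * MOLAR_MASS_AL26
        doses = [DoseEvent(0.0, ident.route, ident.salt_name, 1.0)]
        group_keys = _subject_groups(design)
        per_subject_params: list[PBTKParameters] = []
        if ident.species == "hum" and design.n_subjects > 1:
            per_subject_params = [sample_individual(pop, ref, rng) for _ in group_keys]
        else:
            shared = sample_individual(pop, ref, rng)
            per_subject_params = [shared]

        all_times = np.unique(np.concatenate(
            [[0.0]] + [np.asarray(v, dtype=float) for v in design.sampling_times.values()]))
        results = [simulate(p, ref, doses, all_times) for p in per_subject_params]

        truth.population = pop
        for key, p in zip(group_keys, per_subject_params):
            truth.parameters[key] = p
            truth.references[key] = ref
            truth.doses[key] = doses
            truth.t_grids[key] = all_times

        for matrix, times in design.sampling_times.items():
            unit = design.units[matrix]
            times = np.asarray(times, dtype=float)
            idx = np.searchsorted(all_times, times)
            # per-subject reported values (on the reporting-unit scale)
            subject_values = []
            n_sub = design.n_subjects
            for s in range(n_sub):
                res = results[s % len(results)]
                series = res.series(matrix)[idx]
                reported = np.empty(len(times))
                prev_cum = 0.0
                for j, (t, fid) in enumerate(zip(times, series)):
                    if matrix == "uri" and unit == "g_per_L":
                        inc = fid - prev_cum
                        prev_cum = fid
                        val = fid_to_unit(max(inc, 1e-300), unit, matrix, ref,
                                          dose_g, design.collected_volume_L)
                    else:
                        val = fid_to_unit(fid, unit, matrix, ref, dose_g,
                                          design.collected_volume_L)
                    if pop.sigma_res > 0:
                        val *= np.exp(rng.normal(0.0, pop.sigma_res))
                    reported[j] = val
                subject_values.append(reported)
            subject_values = np.asarray(subject_values)  # (n_sub, n_times)

            for j, t in enumerate(times):
                base = {"identifier": design.identifier, "time_h": float(t),
                        "matrix": matrix, "unit": unit,
                        "dose_mol_per_kg": design.dose_mol_per_kg,
                        "dose_total_mol": dose_total_mol,
                        "complete_collection": True,
                        "collected_volume_L": design.collected_volume_L,
                        "sex": design.sex}
                if design.aggregate:
                    vals = subject_values[:, j]
                    rows.append({**base, "group_id": group_keys[0],
                                 "value": np.nan, "n": n_sub,
                                 "mean": float(vals.mean()),
                                 "sd": float(vals.std(ddof=1))})
                else:
                    for s in range(n_sub):
                        key = group_keys[s] if len(group_keys) > 1 else group_keys[0]
                        rows.append({**base, "group_id": key,
                                     "subject": f"s{s + 1}",
                                     "value": float(subject_values[s, j]),
                                     "n": np.nan, "mean": np.nan, "sd": np.nan})
    records = pd.DataFrame(rows)
    return records, truth


def roundtrip_check(records: pd.DataFrame, truth: GroundTruth, seed=0) -> dict:
    """Curate generated records back to fid and compare with noise-free truth.

    Returns a report with the log-scale residual SD (which should match the
    generating ``sigma_res`` within Monte-Carlo error), the maximum absolute
    log residual, and the number of records compared.
    """
    curated, _ = curate_dataset(records, seed=seed)
    residuals = []
    for (group_id, matrix), sub in curated.groupby(["group_id", "matrix"]):
        pred = truth.predict_fid(group_id, matrix, sub["time_h"].to_numpy())
        obs = sub["value"].to_numpy(dtype=float)
        ok = (pred > 0) & (obs > 0)
        residuals.append(np.log(obs[ok]) - np.log(pred[ok]))
    r = np.concatenate(residuals) if residuals else np.array([])
    return {
        "n_records": int(len(r)),
        "residual_log_sd": float(np.std(r, ddof=1)) if len(r) > 1 else 0.0,
        "max_abs_log_residual": float(np.max(np.abs(r))) if len(r) else 0.0,
        "sigma_res_truth": truth.population.sigma_res,
    }
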