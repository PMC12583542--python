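"""Synthetic TMA cohort generator with planted niche structure.

Real multiplexed TMA cohorts of this kind are access-restricted, so every
downstream stage is exercised on synthetic cohorts whose ground truth is
known. The generator emulates the statistical structure the analysis
assumes, not the imaging physics:

* two centers (A/B) and two histological subtypes (LUAD/LUSC), up to four
  1.5 mm spots per patient;
* cells placed by a Neyman-Scott-style cluster point process: per planted
  prototype, parent seeds fall uniformly in the spot disk with intensity
  proportional to the patient archetype's mixture weight, and cells scatter
  isotropically (Gaussian, prototype sigma) around their parent;
* each cell's 12 marker booleans drawn independently from the prototype's
  marker-probability vector; compartment copied from the prototype;
* per-spot cell counts Poisson with a log-normal patient-level intensity,
  reproducing the right-skewed, heavy-tailed counts seen in real cohorts;
* proportional-hazards survival: event times exponential with rate
  ``baseline_hazard * exp(beta . z)`` where z = (per-prototype cell
  proportions, UICC8 stage); censoring independent exponential calibrated so
  the expected censored fraction equals ``censoring_rate``.

All distributional choices are stand-ins: no generative model exists for the
real data. Ground truth (per-cell planted prototype, per-patient true
hazard) is carried alongside so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CELL_COLUMNS, Dataset, build_dataset
from .markers import MARKERS, N_MARKERS


@dataclass
class Prototype:
    """A planted niche: marker Bernoulli probabilities, compartment, spatial scale."""

    marker_probs: np.ndarray  # (12,) in [0, 1], canonical marker order
    compartment: str
    sigma_um: float  # isotropic Gaussian cluster spread

    def __post_init__(self) -> None:
        self.marker_probs = np.asarray(self.marker_probs, dtype=float)
        if self.marker_probs.shape != (N_MARKERS,):
            raise ValueError(f"marker_probs must have length {N_MARKERS}")
        if ((self.marker_probs < 0) | (self.marker_probs > 1)).any():
            raise ValueError("marker probabilities must lie in [0, 1]")
        if self.sigma_um <= 0:
            raise ValueError("cluster sigma must be positive")


def default_prototypes() -> list[Prototype]:
    """Three well-separated planted niches: carcinoma, lymphocyte, macrophage."""
    probs = {
        # carcinoma-dominant: nearly pure CK with occasional PD-L1
        "carcinoma": dict(CK=0.95, PDL1=0.10),
        # mixed lymphocyte niche: T/B cells with activation/exhaustion states
        "lymphocyte": dict(CD3=0.85, CD4=0.45, CD8=0.30, CD20=0.25, FOXP3=0.08, PD1=0.20, GRB=0.10),
        # TAM niche
        "macrophage": dict(CD68=0.85, CD163=0.50, PDL1=0.05),
    }
    compartments = {"carcinoma": "carcinoma", "lymphocyte": "stroma", "macrophage": "stroma"}
    protos = []
    for name, spec in probs.items():
        vec = np.zeros(N_MARKERS)
        for marker, p in spec.items():
            vec[MARKERS.index(marker)] = p
        protos.append(Prototype(vec, compartments[name], sigma_um=15.0))
    return protos


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    n_patients_per_center_per_subtype: int = 25
    spots_per_patient: int = 4
    spot_diameter_mm: float = 1.5
    planted_prototypes: list[Prototype] = field(default_factory=default_prototypes)
    patient_archetypes: list[np.ndarray] | None = None  # mixture weights over prototypes
    hazard_betas: np.ndarray | None = None  # over (prototype proportions, uicc8 stage)
    baseline_hazard: float = 0.01  # events per month at z = 0
    censoring_rate: float = 0.3
    mean_cells_per_spot: float = 350.0
    cluster_size_mean: float = 30.0  # expected cells per parent seed
    patient_log_sigma: float = 0.5  # log-normal spread of patient-level intensity
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spot_diameter_mm <= 0:
            raise ValueError("spot diameter must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.baseline_hazard < 0:
            raise ValueError("baseline hazard must be nonnegative")
        k = len(self.planted_prototypes)
        if self.patient_archetypes is None:
            # three archetypes spanning carcinoma-heavy to immune-rich mixtures
            base = [
                np.array([0.70, 0.18, 0.12]),
                np.array([0.35, 0.45, 0.20]),
                np.array([0.45, 0.20, 0.35]),
            ]
            if k == 3:
                self.patient_archetypes = base
            else:
                self.patient_archetypes = [np.full(k, 1.0 / k)]
        self.patient_archetypes = [np.asarray(w, dtype=float) for w in self.patient_archetypes]
        for w in self.patient_archetypes:
            if w.shape != (k,):
                raise ValueError("archetype weight length must match prototype count")
            if (w < 0).any() or not np.isclose(w.sum(), 1.0):
                raise ValueError("archetype mixture weights must be nonnegative and sum to 1")
        if self.hazard_betas is None:
            # protective lymphocyte niche, modest stage effect
            beta = np.zeros(k + 1)
            if k >= 2:
                beta[1] = -1.0
            beta[-1] = 0.5
            self.hazard_betas = beta
        self.hazard_betas = np.asarray(self.hazard_betas, dtype=float)
        if self.hazard_betas.shape != (k + 1,):
            raise ValueError("hazard_betas must cover prototype proportions plus stage")


@dataclass
class SyntheticCohort:
    """Generated cohort plus ground truth for scoring recovery."""

    dataset: Dataset
    cell_truth: pd.DataFrame  # cell_id, spot_id, prototype
    patient_truth: pd.DataFrame  # patient_id, archetype_id, true_log_hazard

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        paths = self.dataset.write(out)
        p = out / "truth.tsv"
        self.cell_truth.to_csv(p, sep="\t", index=False)
        paths["truth"] = p
        p2 = out / "truth_patients.tsv"
        self.patient_truth.to_csv(p2, sep="\t", index=False)
        paths["truth_patients"] = p2
        return paths


def _sample_in_disk(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """Uniform points in a disk of given radius centered at the origin."""
    r = radius * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0, 2 * np.pi, size=n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def generate_spot(
    archetype: np.ndarray,
    config: SimulationConfig,
    seed: int,
    intensity: float = 1.0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Generate the cells of one spot.

    Returns a cell table (x_um, y_um, compartment, 12 marker columns) and the
    per-cell planted prototype index.
    """
    archetype = np.asarray(archetype, dtype=float)
    if archetype.size == 0:
        raise ValueError("archetype mixture weights are empty")
    if archetype.shape != (len(config.planted_prototypes),):
        raise ValueError("archetype weight length must match prototype count")
    rng = np.random.default_rng(seed)
    radius_um = config.spot_diameter_mm * 1000.0 / 2.0

    frames: list[pd.DataFrame] = []
    labels: list[np.ndarray] = []
    for p_idx, (weight, proto) in enumerate(zip(archetype, config.planted_prototypes)):
        expected = weight * config.mean_cells_per_spot * intensity
        n_cells = int(rng.poisson(expected))
        n_parents = int(rng.poisson(max(expected / config.cluster_size_mean, 1e-12)))
        if n_cells == 0:
            continue
        n_parents = max(n_parents, 1)
        parents = _sample_in_disk(rng, n_parents, radius_um)
        assignment = rng.integers(0, n_parents, size=n_cells)
        xy = parents[assignment] + rng.normal(scale=proto.sigma_um, size=(n_cells, 2))
        # keep the disk invariant: resample offsets that left the spot
        for _ in range(50):
            outside = np.einsum("ij,ij->i", xy, xy) > radius_um**2
            if not outside.any():
                break
            xy[outside] = parents[assignment[outside]] + rng.normal(
                scale=proto.sigma_um, size=(int(outside.sum()), 2)
            )
        else:  # pragma: no cover - pathological sigma >> radius
            norms = np.linalg.norm(xy, axis=1)
            over = norms > radius_um
            xy[over] *= (radius_um / norms[over])[:, None] * 0.999
        markers = (rng.uniform(size=(n_cells, N_MARKERS)) < proto.marker_probs).astype(np.int8)
        df = pd.DataFrame(markers, columns=list(MARKERS))
        df.insert(0, "x_um", xy[:, 0])
        df.insert(1, "y_um", xy[:, 1])
        df.insert(2, "compartment", proto.compartment)
        frames.append(df)
        labels.append(np.full(n_cells, p_idx))

    if frames:
        cells = pd.concat(frames, ignore_index=True)
        truth = np.concatenate(labels)
    else:
        cells = pd.DataFrame(columns=["x_um", "y_um", "compartment", *MARKERS])
        truth = np.empty(0, dtype=int)
    return cells, truth


def generate_survival(
    patient_features: np.ndarray, config: SimulationConfig, seed: int
) -> tuple[float, int]:
    """Draw (os_months, event) for one patient under proportional hazards.

    Event time T ~ Exponential(rate) with rate = baseline_hazard * exp(beta.z).
    Censoring time C ~ Exponential(rate_c) independent of T with
    ``rate_c = censoring_rate / (1 - censoring_rate) * rate``, which makes
    ``P(C < T) = rate_c / (rate + rate_c) = censoring_rate`` exactly for every
    patient. Returns min(T, C) (floored at 0.01 months) and the event flag.
    """
    z = np.asarray(patient_features, dtype=float)
    if z.shape != config.hazard_betas.shape:
        raise ValueError("feature vector length must match hazard_betas")
    if config.baseline_hazard < 0:
        raise ValueError("baseline hazard must be nonnegative")
    rng = np.random.default_rng(seed)
    rate = config.baseline_hazard * float(np.exp(config.hazard_betas @ z))
    t_event = rng.exponential(1.0 / rate) if rate > 0 else np.inf
    if config.censoring_rate > 0 and rate > 0:
        rate_c = config.censoring_rate / (1.0 - config.censoring_rate) * rate
        t_cens = rng.exponential(1.0 / rate_c)
    else:
        t_cens = np.inf
    os_months = max(min(t_event, t_cens), 0.01)
    event = int(t_event <= t_cens)
    return float(os_months), event


def generate_cohort(config: SimulationConfig, out_dir: str | Path | None = None) -> SyntheticCohort:
    """Assemble a full two-center, two-subtype cohort; optionally write TSVs.

    Archetypes are assigned round-robin within each (center, subtype) block so
    groups stay balanced; all randomness is derived from ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    cell_frames: list[pd.DataFrame] = []
    truth_frames: list[pd.DataFrame] = []
    spot_rows: list[dict] = []
    patient_rows: list[dict] = []
    patient_truth_rows: list[dict] = []
    n_archetypes = len(config.patient_archetypes)
    k = len(config.planted_prototypes)
    nominal_area = np.pi * (config.spot_diameter_mm / 2.0) ** 2

    pat_counter = 0
    spot_counter = 0
    cell_counter = 0
    for center in ("A", "B"):
        for subtype in ("LUAD", "LUSC"):
            for i in range(config.n_patients_per_center_per_subtype):
                pid = f"P{pat_counter:04d}"
                archetype_id = i % n_archetypes
                archetype = config.patient_archetypes[archetype_id]
                # mean-one log-normal patient intensity -> right-skewed counts
                intensity = float(
                    np.exp(rng.normal(0.0, config.patient_log_sigma) - config.patient_log_sigma**2 / 2)
                )
                uicc8 = int(rng.choice([1, 2, 3, 4], p=[0.40, 0.30, 0.22, 0.08]))
                r_status = "1" if rng.uniform() < 0.08 else "0"
                adjuvant = bool(rng.uniform() < 0.15)

                proto_counts = np.zeros(k)
                for _ in range(config.spots_per_patient):
                    sid = f"S{spot_counter:05d}"
                    spot_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
                    cells, truth = generate_spot(archetype, config, spot_seed, intensity)
                    cells = cells.copy()
                    cells.insert(0, "patient_id", pid)
                    cells.insert(1, "spot_id", sid)
                    cell_ids = np.arange(cell_counter, cell_counter + len(cells))
                    cells.insert(0, "cell_id", cell_ids)
                    cell_counter += len(cells)
                    cell_frames.append(cells)
                    truth_frames.append(
                        pd.DataFrame({"cell_id": cell_ids, "spot_id": sid, "prototype": truth})
                    )
                    proto_counts += np.bincount(truth, minlength=k)
                    aligned = float(np.clip(rng.normal(nominal_area, 0.25), 0.3, 3.4))
                    tumor_frac = float(rng.uniform(0.6, 0.95))
                    spot_rows.append(
                        dict(
                            patient_id=pid,
                            spot_id=sid,
                            aligned_area_mm2=round(aligned, 4),
                            tumor_area_mm2=round(aligned * tumor_frac, 4),
                            qc_pass=True,
                        )
                    )
                    spot_counter += 1

                total = proto_counts.sum()
                proportions = proto_counts / total if total > 0 else np.zeros(k)
                z = np.append(proportions, float(uicc8))
                surv_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
                os_months, event = generate_survival(z, config, surv_seed)
                patient_rows.append(
                    dict(
                        patient_id=pid,
                        center=center,
                        subtype=subtype,
                        uicc8=uicc8,
                        r_status=r_status,
                        adjuvant=int(adjuvant),
                        os_months=round(os_months, 3),
                        event=event,
                    )
                )
                patient_truth_rows.append(
                    dict(
                        patient_id=pid,
                        archetype_id=archetype_id,
                        true_log_hazard=float(config.hazard_betas @ z),
                        **{f"true_prop_{j}": proportions[j] for j in range(k)},
                    )
                )
                pat_counter += 1

    if cell_frames:
        cells = pd.concat(cell_frames, ignore_index=True)
        cell_truth = pd.concat(truth_frames, ignore_index=True)
    else:
        cells = pd.DataFrame(columns=["cell_id", *CELL_COLUMNS])
        cell_truth = pd.DataFrame(columns=["cell_id", "spot_id", "prototype"])
    spots = pd.DataFrame(spot_rows, columns=["patient_id", "spot_id", "aligned_area_mm2", "tumor_area_mm2", "qc_pass"])
    patients = pd.DataFrame(
        patient_rows,
        columns=["patient_id", "center", "subtype", "uicc8", "r_status", "adjuvant", "os_months", "event"],
    )
    if patients.empty:
        patients = patients.astype(
            {"uicc8": int, "adjuvant": int, "os_months": float, "event": int}, errors="ignore"
        )
    dataset = build_dataset(cells, spots, patients) if len(patients) else Dataset(cells, spots, patients)
    cohort = SyntheticCohort(dataset, cell_truth, pd.DataFrame(patient_truth_rows))
    if out_dir is not None:
        cohort.write(out_dir)
    return cohort
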