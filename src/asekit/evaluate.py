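"""Logic-readout metrics for endpoint signal matrices.

Raw fluorescence endpoints are normalised per output by the maximum
signal that reporter produced across the whole set of input
combinations (output = 1 at the highest signal).  Normalised signals
above the 0.5 threshold are called ON, otherwise OFF.  Two robustness
metrics summarise each output:

* **VP angle** (vector proximity) — the angle between the vector of
  normalised signals over all 2^N combinations and the ideal 0/1 truth
  vector; 0 degrees is perfect computation.
* **dynamic range** — the separation ``min(ON signals) - max(OFF
  signals)``; positive values certify a clean threshold margin.  A
  ratio variant ``min(ON)/max(OFF)`` is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit import CircuitSpec, TruthTable, truth_table_oracle
from .kinetics import KineticModel, endpoint_signals

__all__ = [
    "normalize_signals",
    "classify",
    "vp_angle",
    "dynamic_range",
    "OutputEvaluation",
    "EvaluationReport",
    "evaluate_circuit",
]

DEFAULT_THRESHOLD = 0.5


def normalize_signals(raw: np.ndarray) -> np.ndarray:
    """Divide each output column by its own maximum over all combinations."""
    raw = np.asarray(raw, dtype=float)
    if raw.ndim == 1:
        raw = raw[:, None]
    if (raw < 0).any():
        raise ValueError("raw signals must be nonnegative")
    maxima = raw.max(axis=0)
    if (maxima == 0).any():
        bad = int(np.flatnonzero(maxima == 0)[0])
        raise ValueError(f"output column {bad} is all zero: no reference maximum")
    return raw / maxima


def classify(normalized: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """ON/OFF calls: strictly above threshold is ON."""
    normalized = np.asarray(normalized, dtype=float)
    if normalized.min() < 0 or normalized.max() > 1:
        raise ValueError("normalized signals must lie in [0, 1]")
    return normalized > threshold


def vp_angle(signal: np.ndarray, truth: np.ndarray) -> float:
    """Angle (degrees) between a signal vector and its 0/1 truth vector."""
    signal = np.asarray(signal, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if signal.shape != truth.shape:
        raise ValueError("signal and truth vectors must have equal length")
    if (signal < 0).any():
        raise ValueError("signal vector must be nonnegative")
    ns, nt = np.linalg.norm(signal), np.linalg.norm(truth)
    if ns == 0 or nt == 0:
        raise ValueError("zero-norm vector has no direction")
    cosine = np.clip(signal @ truth / (ns * nt), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosine)))


def dynamic_range(
    normalized: np.ndarray, truth: np.ndarray, ratio: bool = False
) -> float:
    """Separation between the weakest ON and the strongest OFF signal.

    Default is the difference ``min(ON) - max(OFF)`` on normalised
    signals (at most 1, equal to 1 only for perfectly digital signals);
    ``ratio=True`` returns ``min(ON)/max(OFF)`` instead.
    """
    normalized = np.asarray(normalized, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if normalized.shape != truth.shape:
        raise ValueError("signal and truth vectors must have equal length")
    if truth.all() or not truth.any():
        raise ValueError("truth vector needs at least one ON and one OFF row")
    lo_on = float(normalized[truth].min())
    hi_off = float(normalized[~truth].max())
    if ratio:
        if hi_off == 0:
            return float("inf")
        return lo_on / hi_off
    return lo_on - hi_off


@dataclass
class OutputEvaluation:
    label: str
    normalized: np.ndarray
    calls: np.ndarray  # bool
    expected: np.ndarray  # bool
    vp_angle_deg: float
    dynamic_range: float
    passed: bool


@dataclass
class EvaluationReport:
    input_order: list[str]
    combinations: list[tuple[int, ...]]
    outputs: dict[str, OutputEvaluation]
    threshold: float

    @property
    def passed(self) -> bool:
        return all(o.passed for o in self.outputs.values())

    def to_frame(self):
        import pandas as pd

        records = []
        for i, combo in enumerate(self.combinations):
            rec = dict(zip(self.input_order, combo))
            for label, ev in self.outputs.items():
                rec[f"{label}_signal"] = round(float(ev.normalized[i]), 6)
                rec[f"{label}_call"] = "ON" if ev.calls[i] else "OFF"
                rec[f"{label}_expected"] = "ON" if ev.expected[i] else "OFF"
            records.append(rec)
        return pd.DataFrame.from_records(records)

    def summary(self) -> dict:
        return {
            "passed": bool(self.passed),
            "threshold": self.threshold,
            "outputs": {
                label: {
                    "vp_angle_deg": round(ev.vp_angle_deg, 4),
                    "dynamic_range": round(ev.dynamic_range, 6),
                    "passed": bool(ev.passed),
                }
                for label, ev in self.outputs.items()
            },
        }

    def to_json_dict(self) -> dict:
        d = self.summary()
        d["inputs"] = self.input_order
        d["rows"] = [
            {
                "combination": list(combo),
                **{
                    label: {
                        "signal": float(ev.normalized[i]),
                        "call": bool(ev.calls[i]),
                        "expected": bool(ev.expected[i]),
                    }
                    for label, ev in self.outputs.items()
                },
            }
            for i, combo in enumerate(self.combinations)
        ]
        return d


def evaluate_circuit(
    circuit: CircuitSpec,
    model: KineticModel | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    raw: np.ndarray | None = None,
) -> EvaluationReport:
    """Simulate, normalise, threshold, and score a circuit against its oracle.

    ``raw`` may supply a precomputed endpoint matrix (rows in binary
    counting order) to skip the simulation step.
    """
    model = model or KineticModel()
    table: TruthTable = truth_table_oracle(circuit)
    if raw is None:
        raw = endpoint_signals(circuit, model)
    raw = np.asarray(raw, dtype=float)
    normalized = normalize_signals(raw)
    calls = classify(normalized, threshold)

    outputs: dict[str, OutputEvaluation] = {}
    for j, label in enumerate(circuit.outputs):
        expected = np.array(table.output_vector(label), dtype=bool)
        ev_calls = calls[:, j]
        angle = vp_angle(normalized[:, j], expected.astype(float))
        if expected.all() or not expected.any():
            dr = float("nan")  # no ON/OFF contrast to measure
        else:
            dr = dynamic_range(normalized[:, j], expected)
        outputs[label] = OutputEvaluation(
            label=label,
            normalized=normalized[:, j],
            calls=ev_calls,
            expected=expected,
            vp_angle_deg=angle,
            dynamic_range=dr,
            passed=bool((ev_calls == expected).all()),
        )

    return EvaluationReport(
        input_order=list(table.input_order),
        combinations=[combo for combo, _ in table.rows],
        outputs=outputs,
        threshold=threshold,
    )
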