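"""Light-response detection and dose-response tabulation for MEA spike trains.

The response statistic works on firing rates in 1-s non-overlapping bins
aligned to stimulus onset.  The baseline is the mean and SD of the
per-bin rates over the 30 s preceding the stimulus; the detection
threshold is baseline + 2*SD.  A response starts at the first bin
strictly above threshold and is considered over when the rate has been
at or below threshold for 3 consecutive seconds; the response duration
is the suprathreshold time inside that span (brief sub-threshold dips
shorter than the termination gap stay inside the span but do not count
toward the duration).  A cell is a responder to a stimulus only when its
response lasts longer than 1 s.  The response discharge rate is the mean
rate over the suprathreshold bins minus the baseline rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .mea_sim import Recording, SpikeTrain, StimulusProtocol


@dataclass(frozen=True)
class AnalysisParams:
    """Binning and detection parameters (seconds)."""

    baseline_window_s: float = 30.0
    bin_s: float = 1.0
    termination_gap_s: float = 3.0
    min_response_duration_s: float = 1.0

    def __post_init__(self) -> None:
        if min(self.baseline_window_s, self.bin_s, self.termination_gap_s) <= 0:
            raise ValueError("all analysis windows must be positive")
        if self.min_response_duration_s < 0:
            raise ValueError("minimum duration must be non-negative")
        gap_bins = self.termination_gap_s / self.bin_s
        if abs(gap_bins - round(gap_bins)) > 1e-9:
            raise ValueError("termination gap must be an integer number of bins")

    @property
    def gap_bins(self) -> int:
        return int(round(self.termination_gap_s / self.bin_s))


@dataclass
class ResponseMetrics:
    """Detection result for one (cell, stimulus) pair."""

    cell_id: str
    baseline_rate: float
    baseline_sd: float
    threshold: float
    response_start_s: float | None
    response_duration_s: float
    discharge_rate: float
    responder: bool


def _binned_rates(train: SpikeTrain, t0: float, t1: float, bin_s: float) -> np.ndarray:
    n_bins = int(np.floor((t1 - t0) / bin_s + 1e-9))
    if n_bins <= 0:
        return np.empty(0)
    edges = t0 + np.arange(n_bins + 1) * bin_s
    counts, _ = np.histogram(train.times_s, bins=edges)
    return counts / bin_s


def baseline_stats(
    train: SpikeTrain,
    stimulus_onset_s: float,
    params: AnalysisParams = AnalysisParams(),
) -> tuple[float, float]:
    """Mean and SD of per-bin rates over the window preceding the onset."""
    if stimulus_onset_s < params.baseline_window_s:
        raise ValueError("stimulus onset earlier than the baseline window")
    rates = _binned_rates(
        train, stimulus_onset_s - params.baseline_window_s, stimulus_onset_s, params.bin_s
    )
    if rates.size == 0:
        return 0.0, 0.0
    sd = float(rates.std(ddof=1)) if rates.size > 1 else 0.0
    return float(rates.mean()), sd


def detect_response(
    train: SpikeTrain,
    stimulus_onset_s: float,
    params: AnalysisParams = AnalysisParams(),
    search_end_s: float | None = None,
    latency_window_s: float | None = None,
) -> ResponseMetrics:
    """Detect and time a light response following one stimulus.

    The scan runs from the stimulus onset to ``search_end_s`` (default:
    end of the recording; for multi-stimulus protocols pass the next
    onset minus the baseline window).  ``latency_window_s`` bounds how
    long after onset the response may *start* — a light-evoked response
    is stimulus-locked, so the natural bound is the stimulus duration;
    once started, the response may extend to ``search_end_s``.  ``None``
    leaves the start unbounded.  Spikes after the termination point
    cannot affect the result.
    """
    if not 0 <= stimulus_onset_s <= train.recording_length_s:
        raise ValueError("stimulus lies outside the recording")
    if search_end_s is None:
        search_end_s = train.recording_length_s
    base_rate, base_sd = baseline_stats(train, stimulus_onset_s, params)
    threshold = base_rate + 2.0 * base_sd
    rates = _binned_rates(train, stimulus_onset_s, search_end_s, params.bin_s)

    above = rates > threshold
    if latency_window_s is not None:
        max_start = int(np.ceil(latency_window_s / params.bin_s))
        startable = above.copy()
        startable[max_start:] = False
    else:
        startable = above
    if not startable.any():
        return ResponseMetrics(
            cell_id=train.cell_id,
            baseline_rate=base_rate,
            baseline_sd=base_sd,
            threshold=threshold,
            response_start_s=None,
            response_duration_s=0.0,
            discharge_rate=0.0,
            responder=False,
        )
    start = int(np.argmax(startable))
    gap = params.gap_bins
    # termination: first run of `gap` consecutive sub-threshold bins after start
    end = rates.size
    run = 0
    for i in range(start, rates.size):
        if above[i]:
            run = 0
        else:
            run += 1
            if run == gap:
                end = i - gap + 1  # span ends where the terminating run begins
                break
    span_above = above[start:end]
    duration = float(span_above.sum()) * params.bin_s
    responder = duration > params.min_response_duration_s
    if span_above.any():
        mean_supra = float(rates[start:end][span_above].mean())
        discharge = mean_supra - base_rate
    else:
        discharge = 0.0
    if not responder:
        discharge = 0.0 if duration == 0 else discharge
    return ResponseMetrics(
        cell_id=train.cell_id,
        baseline_rate=base_rate,
        baseline_sd=base_sd,
        threshold=threshold,
        response_start_s=stimulus_onset_s + start * params.bin_s,
        response_duration_s=duration,
        discharge_rate=discharge,
        responder=responder,
    )


def response_discharge_rate(metrics: ResponseMetrics) -> tuple[float, bool]:
    """Baseline-subtracted discharge rate; 0 for non-responders."""
    if not metrics.responder:
        return 0.0, False
    return metrics.discharge_rate, True


def _search_windows(protocol: StimulusProtocol, params: AnalysisParams):
    """Per-stimulus scan windows: to the next onset minus the baseline
    window, or the recording end for the last stimulus."""
    onsets = list(protocol.onsets_s)
    ends = []
    for i, onset in enumerate(onsets):
        if i + 1 < len(onsets):
            ends.append(onsets[i + 1] - params.baseline_window_s)
        else:
            ends.append(protocol.recording_length_s)
    for onset, end in zip(onsets, ends):
        if end <= onset:
            raise ValueError("overlapping analysis windows")
    return list(zip(onsets, ends))


def dose_response(
    recording: Recording,
    params: AnalysisParams = AnalysisParams(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate ResponseMetrics per (cell, stimulus) and per-cell flags.

    Returns ``(table, cells)``: one row per cell and stimulus with the
    detection metrics, and one row per cell with the responder count and
    the dose-dependence flag — positive Spearman correlation between
    discharge rate and log10 irradiance, with at least 2 responding
    stimuli.
    """
    protocol = recording.protocol
    windows = _search_windows(protocol, params)
    log_irr = np.log10(np.asarray(protocol.irradiances))
    rows = []
    for train in recording.trains:
        for stim_idx, (onset, end) in enumerate(windows):
            m = detect_response(
                train,
                onset,
                params,
                search_end_s=end,
                latency_window_s=protocol.durations_s[stim_idx],
            )
            rows.append(
                {
                    "cell_id": train.cell_id,
                    "stimulus": stim_idx,
                    "irradiance": protocol.irradiances[stim_idx],
                    "baseline_rate": m.baseline_rate,
                    "baseline_sd": m.baseline_sd,
                    "threshold": m.threshold,
                    "response_start_s": m.response_start_s,
                    "response_duration_s": m.response_duration_s,
                    "discharge_rate": m.discharge_rate,
                    "responder": m.responder,
                }
            )
    table = pd.DataFrame(rows)
    cell_rows = []
    for cell_id, grp in table.groupby("cell_id", sort=True):
        grp = grp.sort_values("stimulus")
        n_resp = int(grp["responder"].sum())
        rates = grp["discharge_rate"].to_numpy()
        if n_resp >= 2 and np.ptp(rates) > 0:
            rho = spearmanr(rates, log_irr).statistic
            dose_dependent = bool(rho > 0)
        else:
            rho = np.nan
            dose_dependent = False
        cell_rows.append(
            {
                "cell_id": cell_id,
                "n_responding_stimuli": n_resp,
                "spearman_rho": rho,
                "dose_dependent": dose_dependent,
            }
        )
    return table, pd.DataFrame(cell_rows)
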