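"""High-level synthetic experiment drivers.

These reproduce the structure of the validation study on synthetic data:
each participant performs out-of-scanner reference sessions (no motion
artifact; standard processing only, since the reference electrodes carry
no signal) and in-scanner sessions (nonlinear motion artifacts; all three
filtering pipelines).  The drivers return tidy LLR tables ready for the
agreement statistics, plus pipeline ground truth obtained by running the
standard pipeline on the artifact-free signal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .emg import METHODS, LlrTable, process_session
from .emg_sim import EmgSimParams, generate_session_recording
from .protocol import ProtocolSpec, generate_protocol


def _substream(seed: int, *tokens) -> int:
    def encode(t):
        if isinstance(t, str):
            return int.from_bytes(t.encode(), "little")
        return int(t)

    key = [int(seed)] + [encode(t) for t in tokens]
    return int(np.random.SeedSequence(key).generate_state(1)[0] % (2**31))


def simulate_participant_session(
    participant: str,
    session: str,
    seed: int,
    params: EmgSimParams | None = None,
    protocol_spec: ProtocolSpec | None = None,
):
    """One participant-session recording pair with ground truth.

    Out-of-scanner sessions (names starting with ``OUT``) are generated
    without motion artifact.
    """
    params = params or EmgSimParams()
    spec = protocol_spec or ProtocolSpec()
    import dataclasses

    s = _substream(seed, participant, session)
    protocol = generate_protocol(dataclasses.replace(spec, seed=s))
    if session.startswith("OUT"):
        params = dataclasses.replace(params, artifact_gain=0.0)
    recordings, truth = generate_session_recording(
        protocol, params, np.random.default_rng(s + 1)
    )
    return protocol, recordings, truth


def simulate_validation_experiment(
    n_participants: int,
    seed: int,
    sessions=("OUT1", "IN1", "OUT2"),
    params: EmgSimParams | None = None,
    protocol_spec: ProtocolSpec | None = None,
    anfis_config: dict | None = None,
    include_truth: bool = False,
):
    """Synthetic multi-participant validation experiment.

    Returns ``(table, truth_table)``: the H table over all participants,
    sessions and applicable filter methods (``STD`` only outside the
    scanner, all three inside), and -- when ``include_truth`` -- the
    artifact-free pipeline truth for the in-scanner sessions, keyed like
    the main table with filter ``TRUTH``.
    """
    rows, truth_rows = [], []
    for k in range(n_participants):
        pid = f"P{k + 1:02d}"
        for session in sessions:
            protocol, recordings, truth = simulate_participant_session(
                pid, session, seed, params, protocol_spec
            )
            methods = METHODS if session.startswith("IN") else ["STD"]
            rows.extend(
                process_session(
                    recordings, pid, session, methods=methods,
                    anfis_config=anfis_config, seed=_substream(seed, pid, session, "proc"),
                )
            )
            if include_truth and session.startswith("IN"):
                crecs = {m: truth.clean_recording(r) for m, r in recordings.items()}
                for row in process_session(
                    crecs, pid, session, methods=["STD"],
                    seed=_substream(seed, pid, session, "truth"),
                ):
                    row["filter"] = "TRUTH"
                    truth_rows.append(row)
    table = LlrTable.from_rows(rows)
    truth_table = LlrTable.from_rows(truth_rows) if truth_rows else None
    return table, truth_table


def method_error_table(table: LlrTable, truth_table: LlrTable) -> pd.DataFrame:
    """Mean absolute H error of each filtering method against pipeline truth."""
    key = ["participant", "session", "muscle", "velocity", "repetition"]
    truth = truth_table.df.rename(columns={"H": "H_truth"}).drop(columns=["filter"])
    merged = table.df.merge(truth, on=key)
    merged["abs_err"] = (merged["H"] - merged["H_truth"]).abs()
    return merged.groupby("filter")["abs_err"].mean().rename("mean_abs_error").reset_index()


def ranking_study(n_seeds: int, seed: int, anfis_config: dict | None = None) -> pd.DataFrame:
    """Per-seed mean |H - H_truth| of the three pipelines on fresh sessions.

    One in-scanner session per seed under the default study conditions;
    used to check the accuracy ordering ANC < SUB < STD.
    """
    records = []
    for k in range(n_seeds):
        table, truth = simulate_validation_experiment(
            1, _substream(seed, "ranking", k), sessions=("IN1",),
            anfis_config=anfis_config, include_truth=True,
        )
        err = method_error_table(table, truth).set_index("filter")["mean_abs_error"]
        records.append(
            dict(seed=k, ANC=err["ANC"], SUB=err["SUB"], STD=err["STD"],
                 ordered=bool(err["ANC"] < err["SUB"] < err["STD"]))
        )
    return pd.DataFrame(records)
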