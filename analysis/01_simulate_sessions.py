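"""Generate the synthetic DMTS sessions used by the downstream analyses.

Writes four sessions under results/sessions/: a default memory session
(tuned cue responses, weak delay modulation with an independent condition
ranking, 5% incorrect trials), a fixation control with the delay modulation
removed, and a pair of sessions with injected 3-ms lagged synchrony for the
functional-connectivity stage.
"""

from pathlib import Path

from wmv1.pipeline_io import write_session
from wmv1.simulate import SimConfig, fixation_config, simulate_session

OUT = Path("results/sessions")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    base = SimConfig(n_electrodes=8, n_trials_per_condition=200, seed=SEED)
    memory = simulate_session(base, task_id="dmts", session_id="memory")
    write_session(memory, OUT / "memory.h5")
    fixation = simulate_session(fixation_config(base), task_id="fixation",
                                session_id="fixation")
    write_session(fixation, OUT / "fixation.h5")
    synced = SimConfig(
        n_electrodes=8, n_trials_per_condition=100, seed=SEED + 1,
        sync_pairs=[(0, 1, 0.3, 3.0, (700.0, 1700.0)),
                    (2, 3, 0.3, 3.0, (0.0, 200.0))])
    write_session(simulate_session(synced, session_id="synced"),
                  OUT / "synced.h5")
    print(f"wrote {len(list(OUT.glob('*.h5')))} sessions to {OUT}/ "
          f"({memory.n_trials} trials, {len(memory.electrodes)} electrodes each)")


if __name__ == "__main__":
    main()
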