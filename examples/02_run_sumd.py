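"""Run the two-phase supervised protocol on the synthetic complex.

Prints the per-attempt supervision ledger (phase, slope, decision) and a
summary of the stitched binding trajectory.  Takes a couple of minutes on
one CPU; every number is reproducible from the master seed.
"""

import sumdkit as sk

system, start, bound = sk.make_toy_complex()
engine = sk.toy_engine(system)
protocol = sk.default_protocol(system, bound, master_seed=0)

state = sk.EngineState.from_frame(start)
state = engine.equilibrate(state, restraint_k=5.0, duration=50.0, seed=0)

result = sk.run_sumd(
    engine, state, protocol,
    on_record=lambda r: print(
        f"  {r.phase_name:10s} step {r.step_index:2d} attempt {r.attempt_index:2d} "
        f"slope {r.slope:+.4f} Å/ps -> {r.decision.value}"
    ),
)

prod = result.productive_records
print(f"\nstatus: {result.status.value}")
print(f"attempts: {len(result.step_log)}, productive: {len(prod)}")
print(f"stitched frames: {len(result.trajectory)} "
      f"spanning {result.trajectory.times[-1]:.0f} ps of retained dynamics")
print(f"supervised distance: {prod[0].distance_series[0][1]:.1f} Å -> "
      f"{prod[-1].distance_series[-1][1]:.1f} Å")
print("\nA negative slope means the supervised group approached during that "
      "step; only such steps are retained, so the stitched trajectory is an "
      "unbiased (if time-censored) binding pathway.")
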