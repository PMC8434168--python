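"""From raw telemetry to per-session domain scores to trend features.

Scores one participant's plays with the weighted in-game equations,
aggregates them per session and domain on the 10-point scale, and reduces
each domain's session series to mean/slope/intercept features per training
period (total and per difficulty level).
"""

import exerscreen as ex

cfg = ex.CohortConfig(seed=1)
participant = ex.generate_cohort(cfg)[0]
sessions = ex.simulate_sessions(participant, cfg)

# one play, scored by hand
game_id, raw = sessions[0].plays[-1]
unit = ex.score_game(raw, game_id)
print(f"{game_id}: unit score {unit:.3f} -> {ex.normalize_score(unit):.2f} on the 10-point scale")

scores = ex.score_sessions(sessions)
print("\nsession 1 domain scores (game domains 0-10, heart rate bpm, Borg rating):")
print(scores[scores.session_index == 1][["domain", "score"]].round(2).to_string(index=False))

fv = ex.build_feature_vector(
    [ex.DomainScore(**r) for r in scores.to_dict("records")], participant
)
print(f"\nHRMG MeanTotal      {fv.entries['HRMG MeanTotal']:.2f}   (average HRMG score over all 24 sessions)")
print(f"HRMG SlopeLevel3    {fv.entries['HRMG SlopeLevel3']:+.3f} (score change per session within level 3)")
print(f"HRMG InterceptLevel3 {fv.entries['HRMG InterceptLevel3']:.2f}  (estimated score at level-3 entry)")
print("A positive slope means session-to-session improvement within that level.")
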