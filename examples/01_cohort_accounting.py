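"""Per-sweep eligibility accounting from published participation counts.

The eligible sample at each sweep is the total cohort minus members who have
died or emigrated; non-response is only defined over that eligible sample.
This example recomputes eligible samples and non-response percentages from
the raw published counts shipped with the package.
"""

from cohortmi import published_participation, recompute_frames

counts = published_participation()
frames = recompute_frames(counts)

print(f"{'sweep':>5} {'age':>4} {'eligible':>9} {'respondents':>12} {'non-resp %':>11}")
for sweep, row in counts.iterrows():
    fr = frames[sweep]
    print(
        f"{sweep:>5} {row['age']:>4} {fr.eligible_n:>9} "
        f"{fr.respondents_n:>12} {100 * fr.nonresponse_rate:>10.1f}%"
    )

print(
    "\nEach eligible sample equals total - dead - emigrated; by the final "
    "sweep\nnearly half of the surviving resident cohort no longer takes part."
)
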