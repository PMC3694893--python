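"""End-to-end phenotyping of a generated CFSE time course.

Runs all three stages on a well-sampled eight-point course: per-time-point
dye model fitting, repeated integrated population fitting (the dye model
renders each proposal as histograms), then candidate filtering, sensitivity
ranges, agglomerative clustering, and the final resampling filter.

Takes a couple of minutes; lower n_restarts for a quicker look.
"""

from flowmax import RunConfig, phenotype_timecourse
from flowmax.fcyton import PARAM_NAMES
from flowmax.fitting import FAST_SCHEDULE
from flowmax.synthetic import (GeneratorConfig, generate_course,
                               REFERENCE_FLUOR_LOW_CV, REFERENCE_PHENOTYPE)

course = generate_course(truth=(REFERENCE_PHENOTYPE, REFERENCE_FLUOR_LOW_CV),
                         cfg=GeneratorConfig(schedule="eight_point"))

report = phenotype_timecourse(
    course.timecourse,
    RunConfig(n_restarts=40, seed=3, schedule_params=FAST_SCHEDULE,
              final_samples=300),
)

print(f"{len(report.clusters)} non-redundant solution cluster(s)")
best = report.clusters[0]
truth = REFERENCE_PHENOTYPE.to_array()
print(f"best cluster: {len(best.members)} member(s), "
      f"median NPAE {best.median_npae:.2f}%")
print(f"{'param':>8} {'truth':>10} {'low':>10} {'high':>10}")
for i, name in enumerate(PARAM_NAMES):
    lo, hi = best.ranges[name]
    mark = "" if lo <= truth[i] <= hi else "  <- outside"
    print(f"{name:>8} {truth[i]:10.2f} {lo:10.2f} {hi:10.2f}{mark}")

# A well-sampled noise-free course collapses to a single cluster whose
# sensitivity ranges bracket the generating parameters; weakly identified
# death/destiny parameters carry visibly wider ranges.
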