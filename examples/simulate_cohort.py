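"""Simulate a small synthetic cohort and inspect its structure.

Each video emulates the per-frame output of a CNN organ segmenter on a
dynamic transperineal ultrasound: eight probability-map stacks, one per
pelvic organ.  Incorrect-plane videos lose organs according to the defect
mode: anteroposterior displacement removes the anus, rectum and levator ani;
rotation additionally removes the uterus and makes the segmenter noisier on
the organs that remain.
"""

from planeqc import ORGANS, SimCohortConfig, simulate_cohort

config = SimCohortConfig(
    n_correct=4, n_incorrect=4, n_frames=30, height=64, width=64, seed=7
)
videos, labels = simulate_cohort(config)

print(f"{len(videos)} videos of {videos[0].n_frames} frames, "
      f"{videos[0].height}x{videos[0].width} px, 8 organ maps each")
print(f"label rows: {len(labels.organ_correct)} (videos x organs)")
print()
print("per-patient organ labels (1 = correctly visualized) and plane verdict:")
plane = labels.plane_correct()
header = " ".join(f"{o.value[:6]:>6s}" for o in ORGANS)
print(f"{'patient':>8s} {header} {'plane':>6s}")
for video in videos:
    organ_labels = labels.organ_labels(video.patient_id)
    row = " ".join(f"{organ_labels[o]:>6d}" for o in ORGANS)
    print(f"{video.patient_id:>8s} {row} {plane[video.patient_id]:>6d}")

print()
print("A plane is correct only when all eight organs are visualized;")
print("max map value per organ shows presence (confident blob) vs absence:")
video = next(v for v in videos if plane[v.patient_id] == 0)
for organ in ORGANS:
    print(f"  {video.patient_id} {organ.value:>16s}: "
          f"max prob = {float(video.organ_stack(organ).max()):.3f}")
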