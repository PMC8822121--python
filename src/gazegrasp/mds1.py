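"""Optional adapter for the public multimodal grasping dataset (MDS1).

The real recordings are distributed as MATLAB v7.3 containers (one per
subject and exercise) holding, among others:

    ``emg``            samples x 12 double          -> SubjectRecording.emg
    ``restimulus``     samples x 1 relabeled grasp  -> SubjectRecording.emg_labels
    ``gaze``           samples x 2 px + validity    -> SubjectRecording.gaze
    object detections  produced separately by an instance-segmentation
                       network over the first-person video              -> detections

This module documents the field mapping and exposes the subject
exclusion list (S114 is excluded from multimodal analysis because a
strabismus condition degraded the eye-tracking quality).  Loading is
not implemented here: the dataset requires a separate download and the
rest of the package is exercised end to end on synthetic recordings.
"""

from __future__ import annotations

#: Subjects excluded from multimodal analysis (invalid gaze).
EXCLUDED_SUBJECTS: tuple[str, ...] = ("S114",)


def load_subject(path, subject_id: str):
    """Map one subject's MATLAB containers to a SubjectRecording.

    Not implemented: requires the externally downloaded dataset.
    """
    if subject_id in EXCLUDED_SUBJECTS:
        raise ValueError(f"subject {subject_id} is excluded from multimodal analysis")
    raise NotImplementedError(
        "MDS1 loading requires the external dataset; use gazegrasp.synthetic for "
        "protocol-faithful synthetic recordings"
    )
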