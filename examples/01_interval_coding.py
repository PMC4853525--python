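"""Interval coding basics: build a tiny coded video and count content.

A video is coded in successive 10 s windows; each window carries
presence/absence flags for substance x category x channel (e.g.
alcohol/brand/visual).  A content class unions all of a substance's flags
per interval, so several appearances in one window count once.
"""

import numpy as np

from mediareach import CodedVideo, ContentClass, FLAG_COLUMNS, count_content_intervals

col = {name: j for j, name in enumerate(FLAG_COLUMNS)}

# a 95 s video -> ceil(95/10) = 10 coding intervals
mat = np.zeros((10, len(FLAG_COLUMNS)), dtype=bool)
mat[2, col["alcohol.actual_use.visual"]] = True     # drinking shown on screen
mat[2, col["alcohol.brand.visual"]] = True          # branded bottle, same window
mat[5, col["alcohol.implied_use.lyric"]] = True     # sung reference
mat[7, col["tobacco.paraphernalia.visual"]] = True  # ashtray in shot

video = CodedVideo.from_flag_matrix("demo", mat, duration_s=95, title="Demo clip")

alcohol = count_content_intervals(video, ContentClass.alcohol())
tobacco = count_content_intervals(video, ContentClass.tobacco())
print(f"intervals coded:        {video.n_intervals}")
print(f"alcohol intervals:      {alcohol}")
print(f"tobacco intervals:      {tobacco}")
# alcohol = 2, not 3: the two flags in window 2 are one content interval.
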