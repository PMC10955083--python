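"""mpfusion: multi-parametric paired-image fusion classification.

A dual-branch convolutional pipeline for binary tumor-grade classification
from paired two-modality 2-D image slices: independent per-modality feature
extractors, a plug-and-play Multiscale Attention (MA) block, and a
Self-Attention Feature Fusion (SAFF) head that fuses modality tokens with a
class token.  Ships with a synthetic paired-modality cohort generator whose
Bayes-optimal accuracy is computable in closed form, so the whole pipeline
is testable end-to-end without clinical data.
"""

from . import (backbone, fusion_baselines, ma_block, nn, preprocess, saff,
               synthdata, workbench)

__all__ = ["backbone", "fusion_baselines", "ma_block", "nn", "preprocess",
           "saff", "synthdata", "workbench"]
__version__ = "0.1.0"
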