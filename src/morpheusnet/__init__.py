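"""MorpheusNet: a resource-efficient single-channel EEG sleep-stage classifier.

A compact residual depthwise-separable CNN scores 30-second, 100-Hz EEG
epochs into the five AASM stages; a decoupled LSTM re-reads the CNN's
class probabilities over 12-epoch windows to exploit stage-transition
structure.  The architecture comes from a constrained single-level
differentiable search, and an int8 quantization path with fine-tuning
keeps the deployable weight budget under 100 KB.
"""

__version__ = "0.1.0"

from . import data_io, model, nas, nn, quant, synthetic, train

__all__ = ["data_io", "model", "nas", "nn", "quant", "synthetic", "train", "__version__"]
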