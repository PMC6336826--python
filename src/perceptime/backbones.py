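"""Optional pretrained-classifier feature extractor.

The reference configuration reads activations from an ImageNet-pretrained
AlexNet at conv2, pool5, fc7 and the softmax output.  torch/torchvision are
deliberately an optional extra (``pip install perceptime[backbone]``): the
rest of the package, including the full test suite, runs without them via
the random-projection and pixel-identity extractors.
"""

from __future__ import annotations

from typing import Dict, Sequence

import numpy as np

from .features import DEFAULT_LAYERS, ConfigurationError, LayerSpec

__all__ = ["AlexNetExtractor"]

# Index of each canonical read-out inside torchvision's AlexNet graph.
_ALEXNET_TAPS = {
    "conv2": ("features", 3),   # ReLU after the second conv stage
    "pool5": ("features", 12),  # final max-pool
    "fc7": ("classifier", 5),   # ReLU after the second fully connected layer
    "output": ("softmax", None),
}


class AlexNetExtractor:
    """Per-frame activation read-out from a pretrained AlexNet.

    Frames are resized to the network's native 224x224 input with bilinear
    interpolation (configurable via ``input_size``) and normalised with the
    standard ImageNet statistics.  Activations are flattened channel-major.
    """

    def __init__(
        self,
        layers: Sequence[LayerSpec] = DEFAULT_LAYERS,
        input_size: int = 224,
        device: str = "cpu",
    ):
        try:
            import torch
            import torchvision
        except ImportError as exc:  # pragma: no cover - optional extra
            raise ImportError(
                "AlexNetExtractor requires the optional 'backbone' extra "
                "(pip install perceptime[backbone])"
            ) from exc
        for sp in layers:
            if sp.name not in _ALEXNET_TAPS:
                raise ConfigurationError(
                    f"unknown AlexNet read-out {sp.name!r}; "
                    f"available: {sorted(_ALEXNET_TAPS)}"
                )
        self._torch = torch
        self.layers = tuple(layers)
        self.extractor_id = "alexnet_imagenet"
        self.input_size = input_size
        self.device = device
        self._model = torchvision.models.alexnet(weights="IMAGENET1K_V1")
        self._model.eval().to(device)
        self._mean = torch.tensor([0.485, 0.456, 0.406]).view(3, 1, 1)
        self._std = torch.tensor([0.229, 0.224, 0.225]).view(3, 1, 1)

    def _preprocess(self, frame: np.ndarray):
        torch = self._torch
        x = torch.from_numpy(np.asarray(frame, dtype=np.float32) / 255.0)
        x = x.permute(2, 0, 1)
        x = torch.nn.functional.interpolate(
            x.unsqueeze(0),
            size=(self.input_size, self.input_size),
            mode="bilinear",
            align_corners=False,
        )
        return ((x.squeeze(0) - self._mean) / self._std).unsqueeze(0).to(self.device)

    def __call__(self, frame: np.ndarray) -> Dict[str, np.ndarray]:
        torch = self._torch
        wanted = {sp.name for sp in self.layers}
        out: Dict[str, np.ndarray] = {}
        with torch.no_grad():
            x = self._preprocess(frame)
            for i, mod in enumerate(self._model.features):
                x = mod(x)
                for name in ("conv2", "pool5"):
                    tap = _ALEXNET_TAPS[name]
                    if name in wanted and tap == ("features", i):
                        out[name] = x.flatten().cpu().numpy().astype(np.float64)
            x = self._model.avgpool(x)
            x = torch.flatten(x, 1)
            for i, mod in enumerate(self._model.classifier):
                x = mod(x)
                if "fc7" in wanted and _ALEXNET_TAPS["fc7"] == ("classifier", i):
                    out["fc7"] = x.flatten().cpu().numpy().astype(np.float64)
            if "output" in wanted:
                probs = torch.softmax(x, dim=1)
                out["output"] = probs.flatten().cpu().numpy().astype(np.float64)
        return out
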