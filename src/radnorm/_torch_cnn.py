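"""Optional reference CNN classifier (requires torch).

Three convolution + ReLU + max-pool stages, two fully connected layers and a
softmax head (~1.2M parameters at 256x256 input), trained with Adam and
cross-entropy under the shared ExperimentConfig.  This module is never
imported unless torch is installed; the bundled test suite relies on the
fast fallback classifiers instead.
"""

from __future__ import annotations

import numpy as np
import torch
from torch import nn

from radnorm.bench_harness import ExperimentConfig


class _Net(nn.Module):
    def __init__(self, input_size: tuple[int, int]):
        super().__init__()
        self.features = nn.Sequential(
            nn.Conv2d(1, 16, 3, padding=1), nn.ReLU(), nn.MaxPool2d(2),
            nn.Conv2d(16, 32, 3, padding=1), nn.ReLU(), nn.MaxPool2d(2),
            nn.Conv2d(32, 32, 3, padding=1), nn.ReLU(), nn.MaxPool2d(2),
        )
        h, w = input_size[0] // 8, input_size[1] // 8
        self.classifier = nn.Sequential(
            nn.Flatten(), nn.Linear(32 * h * w, 64), nn.ReLU(), nn.Linear(64, 2),
        )

    def forward(self, x):
        return self.classifier(self.features(x))


class LightweightCNNClassifier:
    """ClassifierContract implementation backed by the reference CNN."""

    def __init__(self) -> None:
        self._net: _Net | None = None

    def fit(self, images, labels, config: ExperimentConfig, rng: np.random.Generator):
        torch.manual_seed(int(rng.integers(2**31)))
        X = torch.as_tensor(np.asarray(images), dtype=torch.float32).unsqueeze(1)
        y = torch.as_tensor(np.asarray(labels), dtype=torch.long)
        self._net = _Net((X.shape[2], X.shape[3]))
        opt = torch.optim.Adam(
            self._net.parameters(),
            lr=config.learning_rate,
            weight_decay=config.weight_decay,
        )
        loss_fn = nn.CrossEntropyLoss()
        n = len(X)
        batch = min(config.batch_size, n)
        self._net.train()
        for _ in range(config.max_epochs):
            perm = torch.as_tensor(rng.permutation(n))
            for start in range(0, n, batch):
                idx = perm[start : start + batch]
                opt.zero_grad()
                loss = loss_fn(self._net(X[idx]), y[idx])
                loss.backward()
                opt.step()
        self._net.eval()
        return self

    def predict_proba(self, images) -> np.ndarray:
        X = torch.as_tensor(np.asarray(images), dtype=torch.float32).unsqueeze(1)
        with torch.no_grad():
            logits = self._net(X)
        return torch.softmax(logits, dim=1)[:, 1].numpy()

    def loss(self, images, labels) -> float:
        X = torch.as_tensor(np.asarray(images), dtype=torch.float32).unsqueeze(1)
        y = torch.as_tensor(np.asarray(labels), dtype=torch.long)
        with torch.no_grad():
            return float(nn.CrossEntropyLoss()(self._net(X), y).item())
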