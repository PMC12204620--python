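"""Optional torch-backed image classifier (224x224x3 spectrogram images).

Four convolution blocks (32/128/128/128 filters, configurable square
kernel, ReLU, 2x2 max-pooling), a 1024-unit dense layer, and a softmax-2
head; inputs are scaled by 1/255 and labels one-hot encoded.  Imported
lazily -- torch is an optional dependency.
"""

from __future__ import annotations

import numpy as np


class _TorchCnnModel:
    def __init__(self, net, classes, device):
        self._net = net
        self.classes_ = classes
        self._device = device

    def predict(self, X: np.ndarray) -> np.ndarray:
        import torch

        self._net.eval()
        with torch.no_grad():
            t = torch.as_tensor(np.asarray(X, dtype=np.float32) / 255.0).permute(0, 3, 1, 2)
            logits = self._net(t.to(self._device))
            idx = logits.argmax(dim=1).cpu().numpy()
        return self.classes_[idx]


def fit_cnn(config, X: np.ndarray, y: np.ndarray):
    import torch
    from torch import nn

    torch.manual_seed(config.seed)
    device = torch.device("cpu")
    classes, y_idx = np.unique(y, return_inverse=True)
    if len(classes) != 2:
        raise ValueError("cnn backend expects exactly two classes")

    layers: list[nn.Module] = []
    in_ch = 3
    size = config.cnn_input_shape[0]
    for filters in config.cnn_filters:
        layers += [
            nn.Conv2d(in_ch, filters, config.cnn_kernel, padding="same"),
            nn.ReLU(),
            nn.MaxPool2d(2),
        ]
        in_ch = filters
        size //= 2
    layers += [nn.Flatten(), nn.Linear(in_ch * size * size, config.cnn_dense), nn.ReLU(),
               nn.Linear(config.cnn_dense, 2)]
    net = nn.Sequential(*layers).to(device)
    opt = torch.optim.Adam(net.parameters())
    loss_fn = nn.CrossEntropyLoss()

    Xt = torch.as_tensor(np.asarray(X, dtype=np.float32) / 255.0).permute(0, 3, 1, 2)
    yt = torch.as_tensor(y_idx, dtype=torch.long)
    ds = torch.utils.data.TensorDataset(Xt, yt)
    loader = torch.utils.data.DataLoader(ds, batch_size=config.cnn_batch_size, shuffle=True,
                                         generator=torch.Generator().manual_seed(config.seed))
    net.train()
    for _ in range(config.cnn_epochs):
        for xb, yb in loader:
            opt.zero_grad()
            loss = loss_fn(net(xb.to(device)), yb.to(device))
            loss.backward()
            opt.step()
    return _TorchCnnModel(net, classes, device)
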