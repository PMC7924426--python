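"""HOG + SVM backend: a conventional-classifier alternative to the DCNN.

Each 224 x 224 representative image is described by a histogram of
oriented gradients; a multi-class support vector machine (one-vs-one) is
fitted with its regularization selected by five-fold cross-validation.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from skimage.feature import hog
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

HOG_PARAMS = dict(orientations=9, pixels_per_cell=(16, 16), cells_per_block=(2, 2))


class HogSvmError(Exception):
    pass


def hog_features(images: Sequence) -> np.ndarray:
    feats = []
    for img in images:
        px = np.asarray(getattr(img, "pixels", img), dtype=np.float64)
        feats.append(hog(px, **HOG_PARAMS))
    return np.asarray(feats)


def hog_svm_classify(
    train_images: Sequence,
    train_labels: Sequence[int],
    test_images: Sequence,
    folds: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Predict labels for ``test_images`` with a cross-validated HOG+SVM."""
    y = np.asarray([int(l) for l in train_labels])
    if len(np.unique(y)) < 2:
        raise HogSvmError("training requires at least 2 classes")
    x_train = hog_features(train_images)
    x_test = hog_features(test_images)
    n_min = int(np.bincount(y).min())
    cv = StratifiedKFold(n_splits=min(folds, n_min), shuffle=True, random_state=seed)
    model = GridSearchCV(
        Pipeline(
            [
                ("scale", StandardScaler()),
                ("svm", SVC(kernel="rbf", gamma="scale", decision_function_shape="ovo", random_state=seed)),
            ]
        ),
        param_grid={"svm__C": [0.1, 1.0, 10.0, 100.0]},
        cv=cv,
        n_jobs=1,
    )
    model.fit(x_train, y)
    return model.predict(x_test)
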