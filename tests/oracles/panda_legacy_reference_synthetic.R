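# Synthetic stand-in reference for legacy PANDA message passing.
#
# This is an independently hand-coded R transliteration of the legacy
# update equations (combined row/column z-score normalisation, continuous
# Tanimoto kernel, responsibility/availability averaging, diagonal refill
# sd * n * exp(2*alpha*step), convergence on mean |W - (R+A)/2|).
# It exists only as a cross-check oracle for the Python implementation:
# same equations, different language, independent coding and BLAS.
#
# Usage: Rscript panda_legacy_reference_synthetic.R motif.tsv ppi.tsv \
#          coexpr.tsv alpha tolerance max_iter out.tsv
# Inputs are headerless numeric TSV matrices; output is the final W
# written with full precision.

args <- commandArgs(trailingOnly = TRUE)
motif <- as.matrix(read.table(args[1], sep = "\t"))
ppi <- as.matrix(read.table(args[2], sep = "\t"))
coexpr <- as.matrix(read.table(args[3], sep = "\t"))
alpha <- as.numeric(args[4])
tolerance <- as.numeric(args[5])
max_iter <- as.integer(args[6])
out_path <- args[7]

t_normalize <- function(M) {
  pop_sd <- function(x) sqrt(mean((x - mean(x))^2))
  row_mu <- apply(M, 1, mean); row_sd <- apply(M, 1, pop_sd)
  col_mu <- apply(M, 2, mean); col_sd <- apply(M, 2, pop_sd)
  zrow <- sweep(M, 1, row_mu, "-")
  zrow <- sweep(zrow, 1, ifelse(row_sd > 0, row_sd, Inf), "/")
  zcol <- sweep(M, 2, col_mu, "-")
  zcol <- sweep(zcol, 2, ifelse(col_sd > 0, col_sd, Inf), "/")
  (zrow + zcol) / sqrt(2)
}

tanimoto <- function(X, Y) {
  A <- X %*% Y
  row_norm <- rowSums(X * X)
  col_norm <- colSums(Y * Y)
  den <- sqrt(pmax(outer(row_norm, col_norm, "+") - abs(A), 1e-10))
  A / den
}

update_diagonal <- function(M, num, alpha, step) {
  diag(M) <- NA
  sds <- apply(M, 1, sd, na.rm = TRUE)  # sample sd, ddof = 1
  sds[is.na(sds)] <- 0
  diag(M) <- sds * num * exp(2 * alpha * step)
  M
}

W <- t_normalize(motif)
P <- t_normalize(ppi)
C <- t_normalize(coexpr)
n_tfs <- nrow(motif)
n_genes <- ncol(motif)

hamming <- Inf
step <- 0
while (hamming > tolerance && step < max_iter) {
  R <- tanimoto(P, W)
  A <- tanimoto(W, t(C))
  candidate <- 0.5 * (R + A)
  hamming <- mean(abs(W - candidate))
  W <- (1 - alpha) * W + alpha * candidate
  if (hamming > tolerance) {
    P <- (1 - alpha) * P + alpha * update_diagonal(tanimoto(W, t(W)), n_tfs, alpha, step)
    C <- (1 - alpha) * C + alpha * update_diagonal(tanimoto(t(W), W), n_genes, alpha, step)
  }
  step <- step + 1
}

write.table(format(W, digits = 17, scientific = TRUE),
            out_path, sep = "\t", quote = FALSE,
            row.names = FALSE, col.names = FALSE)
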