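#!/usr/bin/env Rscript
# Bridge script: run the BUGS model in <workdir> with rjags and dump draws.
# Usage: Rscript _jags_run.R <workdir>
# Expects model.bug, data.json, inits.json, settings.json; writes chain_<c>.csv.

suppressPackageStartupMessages({
  library(rjags)
  library(jsonlite)
})

args <- commandArgs(trailingOnly = TRUE)
wd <- args[[1]]

data <- fromJSON(file.path(wd, "data.json"))
data <- lapply(data, function(x) if (is.list(x)) do.call(rbind, x) else x)
settings <- fromJSON(file.path(wd, "settings.json"))
inits_raw <- fromJSON(file.path(wd, "inits.json"), simplifyDataFrame = FALSE)

fix_inits <- function(ch) {
  rng_name <- ch[[".RNG.name"]]
  rng_seed <- ch[[".RNG.seed"]]
  ch[[".RNG.name"]] <- NULL
  ch[[".RNG.seed"]] <- NULL
  ch <- lapply(ch, function(x) {
    x <- unlist(lapply(x, function(v) if (is.null(v)) NA_real_ else v))
    as.numeric(x)
  })
  ch[[".RNG.name"]] <- rng_name
  ch[[".RNG.seed"]] <- as.integer(rng_seed)
  ch
}
inits <- lapply(inits_raw, fix_inits)

model <- jags.model(
  file.path(wd, "model.bug"),
  data = data,
  inits = inits,
  n.chains = settings$n_chains,
  n.adapt = settings$n_adapt,
  quiet = TRUE
)
if (settings$burn_in > 0) update(model, settings$burn_in)
samples <- coda.samples(
  model,
  variable.names = settings$monitors,
  n.iter = settings$n_iter,
  thin = settings$thin
)
for (c in seq_len(settings$n_chains)) {
  write.csv(as.matrix(samples[[c]]), file.path(wd, sprintf("chain_%d.csv", c)),
            row.names = FALSE)
}
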