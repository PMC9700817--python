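# Frozen architecture dimensions.
#
# The printed trainable-parameter totals of the four production models are
# part of the package contract; the dimensions below were fixed once so
# that each total is reproduced exactly, and must not be changed without
# revising the contract.  Arithmetic breakdown (weights include biases;
# LSTM layers carry both input-to-hidden and hidden-to-hidden biases):
#
# RT model (total 708,224):
#   aa embedding 27x29                                =     783
#   PTM other-element projection 22->2 (no bias)      =      44
#   conv1d 37->97, k=7 (+bias)                        =  25,220
#   BiLSTM layer 1: in 134 (=37+97), 128/direction    = 270,336
#   BiLSTM layer 2: in 256, 128/direction             = 395,264
#   decoder 256->64 (+bias), PReLU(64), 64->1 (+bias) =  16,577
#
# CCS model (total 713,452 = RT + 5,228):
#   charge embedding 11x2 concatenated at input       =      22
#   conv + BiLSTM-1 widening for 2 extra channels     =   3,406
#   charge embedding 11x24 at the pooled decoder      =     264
#   decoder widening 256->280 input                   =   1,536
#
# MS2 model (total 3,988,974):
#   aa embedding 27x237                               =   6,399
#   PTM other-element projection 22->2                =      44
#   meta net 16->11 (+bias)                           =     187
#   5 transformer layers (4 + 1 modloss), d=256,
#     8 heads, FFN 1024, post-norm                    = 3,948,800
#   main decoder 256->64, PReLU(64), 64->4            =  16,772
#   modloss decoder 256->64, PReLU(64), 64->4         =  16,772
#   (sinusoidal positional encoding: no parameters)
#
# HLA classifier (total 1,669,697):
#   ascii embedding 128x249                           =  31,872
#   conv1d 249->208, k=7 (+bias)                      = 362,752
#   LSTM layer 1 (unidirectional): in 457, h=256      = 732,160
#   LSTM layer 2 (unidirectional): in 256, h=256      = 526,336
#   decoder 256->64, PReLU(64), 64->1                 =  16,577

common:
  aa_vocab: 27
  mod_raw_dim: 28        # 6 CHNOSP + 22 other elements
  ptm_feature_dim: 8     # 6 raw CHNOSP + 2 projected
  max_charge: 10
  instruments: [QE, Lumos, timsTOF, SciexTOF, unknown]
  decoder_hidden: 64

ms2:
  d_model: 256
  aa_embed_dim: 237
  meta_dim: 11
  n_heads: 8
  ffn_dim: 1024
  n_layers: 4
  n_modloss_layers: 1
  n_main_channels: 4
  n_modloss_channels: 4

rt:
  aa_embed_dim: 29
  conv_channels: 97
  conv_kernel: 7
  lstm_hidden: 128       # per direction; bidirectional output is 256
  lstm_layers: 2

ccs:
  charge_input_dim: 2    # Embedding(11, 2) concatenated per position
  charge_decoder_dim: 24 # Embedding(11, 24) concatenated to the pooled state

hla:
  vocab: 128             # raw ASCII codes
  aa_embed_dim: 249
  conv_channels: 208
  conv_kernel: 7
  lstm_hidden: 256       # unidirectional
  lstm_layers: 2
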